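"""From per-base counts to SNP-masked mutation calls and region summaries.

The input currency is the per-base count table (TSV header
``region_id  pos  ref  depth  A  C  G  T``, 0-based region-local positions).
Frequencies are depth-weighted: the "sequenced length" of a set of positions
is the sum of their depths, so a frequency is events per sequenced base.
Region summaries carry every term of the three mutation-frequency formulas:

* total frequency        = total mutations / total sequenced length
* C/G frequency          = (mutated C + mutated G) / (seq length C + seq length G)
* hotspot C/G frequency  = same, restricted to C in hotspot motifs on the
  plus frame and G in hotspot motifs on the minus frame.

The AID-null (*Aicda-/-*) genotype defines the background: per-site or
per-region control frequencies are subtracted (floored at zero) before any
figure-level comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_regions import TargetRegion

logger = logging.getLogger(__name__)

__all__ = [
    "COUNTS_COLUMNS",
    "RegionMutationSummary",
    "read_counts",
    "write_counts",
    "load_snp_mask",
    "mask_snps",
    "tally_mutations",
    "subtract_control",
    "summarize_region",
    "summarize_regions",
    "site_transition_frequencies",
    "per_base_profile",
]

COUNTS_COLUMNS = ["region_id", "pos", "ref", "depth", "A", "C", "G", "T"]
BASES = ("A", "C", "G", "T")
TRANSITIONS = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-base count TSV and validate its schema."""
    table = pd.read_csv(path, sep="\t", dtype={"region_id": str, "ref": str})
    missing = [c for c in COUNTS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    return table[COUNTS_COLUMNS]


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


def load_snp_mask(
    path: str | Path, regions: Iterable[TargetRegion]
) -> dict[str, set[int]]:
    """Read a germline SNP mask (BED or VCF) into region-local positions.

    BED intervals are 0-based half-open; every covered base inside a region
    is masked.  VCF positions (1-based) are converted to 0-based.  Positions
    are matched to regions by contig and genomic coordinate.
    """
    path = Path(path)
    by_chrom: dict[str, list[TargetRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)
    mask: dict[str, set[int]] = {r.region_id: set() for rs in by_chrom.values() for r in rs}

    def add(chrom: str, genomic_pos: int) -> None:
        for region in by_chrom.get(chrom, ()):
            if region.start <= genomic_pos < region.end:
                mask[region.region_id].add(genomic_pos - region.start)

    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for record in vcf:
                add(record.chrom, record.pos - 1)
    else:
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                for genomic_pos in range(start, end):
                    add(chrom, genomic_pos)
    return mask


def _normalize_snp_positions(
    snp_positions: Mapping[str, Iterable[int]] | Iterable[tuple[str, int]] | None,
) -> set[tuple[str, int]]:
    if not snp_positions:
        return set()
    if isinstance(snp_positions, Mapping):
        return {(rid, int(p)) for rid, ps in snp_positions.items() for p in ps}
    return {(rid, int(p)) for rid, p in snp_positions}


def mask_snps(
    counts: pd.DataFrame,
    snp_positions: Mapping[str, Iterable[int]] | Iterable[tuple[str, int]] | None,
    vaf_threshold: float | None = None,
) -> pd.DataFrame:
    """Suppress annotated SNP positions (and, optionally, high-VAF sites).

    Rows at ``snp_positions`` are removed; if ``vaf_threshold`` is set, rows
    whose maximum non-reference allele fraction reaches the threshold are
    removed as well.  The number of suppressed rows is logged.
    """
    snp_set = _normalize_snp_positions(snp_positions)
    keep = np.ones(len(counts), dtype=bool)
    if snp_set:
        index = pd.MultiIndex.from_arrays([counts["region_id"], counts["pos"]])
        keep &= ~index.isin(list(snp_set))
    if vaf_threshold is not None:
        base_counts = counts[list(BASES)].to_numpy(dtype=float)
        depth = counts["depth"].to_numpy(dtype=float)
        ref_idx = pd.Categorical(
            counts["ref"], categories=list(BASES)
        ).codes.astype(int)
        valid = ref_idx >= 0
        alt = base_counts.copy()
        alt[valid, ref_idx[valid]] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(depth > 0, alt.max(axis=1) / depth, 0.0)
        keep &= vaf < vaf_threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("mask_snps: suppressed %d of %d positions", removed, len(counts))
    return counts.loc[keep].reset_index(drop=True)


def tally_mutations(
    counts: pd.DataFrame,
    min_alt_count: int = 1,
    annotation: Mapping[str, Mapping[int, set[tuple[str, str]]]] | None = None,
) -> pd.DataFrame:
    """One mutation call per (position, non-reference base) with enough reads.

    Returns columns ``region_id, pos, ref, alt, alt_count, depth,
    change_label, change_class, c_frame_strand, hotspot_memberships``.
    ``c_frame_strand`` is '+' at reference C, '-' at reference G (the
    deaminated C sits on the minus strand) and empty otherwise.  Reference-N
    rows are skipped.
    """
    rows = counts[counts["ref"].isin(BASES)]
    parts = []
    for alt in BASES:
        sub = rows[(rows["ref"] != alt) & (rows[alt] >= min_alt_count)]
        if len(sub):
            parts.append(
                pd.DataFrame(
                    {
                        "region_id": sub["region_id"].to_numpy(),
                        "pos": sub["pos"].to_numpy(),
                        "ref": sub["ref"].to_numpy(),
                        "alt": alt,
                        "alt_count": sub[alt].to_numpy(),
                        "depth": sub["depth"].to_numpy(),
                    }
                )
            )
    if not parts:
        sites = pd.DataFrame(
            columns=["region_id", "pos", "ref", "alt", "alt_count", "depth"]
        )
    else:
        sites = pd.concat(parts, ignore_index=True)
        sites = sites.sort_values(["region_id", "pos", "alt"]).reset_index(drop=True)
    sites["change_label"] = sites["ref"].astype(str) + ">" + sites["alt"].astype(str)
    sites["change_class"] = [
        "transition" if (r, a) in TRANSITIONS else "transversion"
        for r, a in zip(sites["ref"], sites["alt"])
    ]
    sites["c_frame_strand"] = sites["ref"].map({"C": "+", "G": "-"}).fillna("")
    if annotation is not None:
        sites["hotspot_memberships"] = [
            sorted(annotation.get(rid, {}).get(pos, set()))
            for rid, pos in zip(sites["region_id"], sites["pos"])
        ]
    else:
        sites["hotspot_memberships"] = [[] for _ in range(len(sites))]
    return sites


def subtract_control(
    case_freqs: pd.Series, control_freqs: pd.Series
) -> pd.Series:
    """Per-site ``max(case - control, 0)``.

    Both inputs are Series indexed by (region_id, pos).  Sites present only
    in the case are kept with control treated as 0 (a warning is logged);
    sites present only in the control are ignored.
    """
    control = control_freqs.reindex(case_freqs.index)
    n_missing = int(control.isna().sum())
    if n_missing:
        logger.warning(
            "subtract_control: %d case sites missing from control (treated as 0)",
            n_missing,
        )
    adjusted = (case_freqs - control.fillna(0.0)).clip(lower=0.0)
    return adjusted


@dataclass
class RegionMutationSummary:
    """Every term of the mutation-frequency formulas for one region.

    Numerators are read-level events (summed alternate-base calls);
    denominators are depth-weighted sequenced lengths.  ``flags`` records
    zero-denominator frequencies that were reported as 0.
    """

    region_id: str
    total_mutations: int = 0
    total_sequenced_length: int = 0
    mutated_cytosines: int = 0
    mutated_guanines: int = 0
    seq_length_cytosines: int = 0
    seq_length_guanines: int = 0
    mutated_cytosines_hotspot: int = 0
    mutated_guanines_hotspot: int = 0
    seq_length_cytosines_hotspot: int = 0
    seq_length_guanines_hotspot: int = 0
    ct_transition_mutations: int = 0
    flags: list[str] = field(default_factory=list)

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            if name not in self.flags:
                self.flags.append(name)
            return 0.0
        return num / den

    @property
    def total_freq(self) -> float:
        return self._ratio(self.total_mutations, self.total_sequenced_length, "total_freq")

    @property
    def cg_freq(self) -> float:
        return self._ratio(
            self.mutated_cytosines + self.mutated_guanines,
            self.seq_length_cytosines + self.seq_length_guanines,
            "cg_freq",
        )

    @property
    def hotspot_freq(self) -> float:
        return self._ratio(
            self.mutated_cytosines_hotspot + self.mutated_guanines_hotspot,
            self.seq_length_cytosines_hotspot + self.seq_length_guanines_hotspot,
            "hotspot_freq",
        )

    @property
    def ct_freq(self) -> float:
        return self._ratio(
            self.ct_transition_mutations,
            self.seq_length_cytosines + self.seq_length_guanines,
            "ct_freq",
        )


def _hotspot_position_sets(
    annotation: Mapping[int, set[tuple[str, str]]] | None,
) -> tuple[set[int], set[int]]:
    """Positions carrying a '+' instance (C frame) and a '-' instance (G frame)."""
    plus: set[int] = set()
    minus: set[int] = set()
    for pos, members in (annotation or {}).items():
        for _, strand in members:
            (plus if strand == "+" else minus).add(pos)
    return plus, minus


def summarize_region(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    annotation: Mapping[int, set[tuple[str, str]]] | None = None,
    region_id: str | None = None,
) -> RegionMutationSummary:
    """Depth-weighted frequency accounting for one region.

    ``sites`` are mutation calls tallied from the same (SNP-masked)
    ``counts``.  Reference-N positions are excluded from all denominators.
    Hotspot terms restrict to positions carrying a '+' hotspot instance
    (cytosines) or a '-' instance (guanines).
    """
    if region_id is None:
        ids = counts["region_id"].unique()
        if len(ids) != 1:
            raise ValueError("summarize_region needs a single region (or region_id=)")
        region_id = str(ids[0])
    counts = counts[counts["region_id"] == region_id]
    sites = sites[sites["region_id"] == region_id] if len(sites) else sites

    valid = counts[counts["ref"].isin(BASES)]
    summary = RegionMutationSummary(region_id=region_id)
    summary.total_sequenced_length = int(valid["depth"].sum())
    c_rows = valid[valid["ref"] == "C"]
    g_rows = valid[valid["ref"] == "G"]
    summary.seq_length_cytosines = int(c_rows["depth"].sum())
    summary.seq_length_guanines = int(g_rows["depth"].sum())

    plus_hot, minus_hot = _hotspot_position_sets(annotation)
    summary.seq_length_cytosines_hotspot = int(
        c_rows[c_rows["pos"].isin(plus_hot)]["depth"].sum()
    )
    summary.seq_length_guanines_hotspot = int(
        g_rows[g_rows["pos"].isin(minus_hot)]["depth"].sum()
    )

    if len(sites):
        summary.total_mutations = int(sites["alt_count"].sum())
        at_c = sites[sites["ref"] == "C"]
        at_g = sites[sites["ref"] == "G"]
        summary.mutated_cytosines = int(at_c["alt_count"].sum())
        summary.mutated_guanines = int(at_g["alt_count"].sum())
        summary.mutated_cytosines_hotspot = int(
            at_c[at_c["pos"].isin(plus_hot)]["alt_count"].sum()
        )
        summary.mutated_guanines_hotspot = int(
            at_g[at_g["pos"].isin(minus_hot)]["alt_count"].sum()
        )
        summary.ct_transition_mutations = int(
            at_c[at_c["alt"] == "T"]["alt_count"].sum()
            + at_g[at_g["alt"] == "A"]["alt_count"].sum()
        )
    return summary


def summarize_regions(
    counts: pd.DataFrame,
    annotations: Mapping[str, Mapping[int, set[tuple[str, str]]]] | None = None,
    min_alt_count: int = 1,
) -> dict[str, RegionMutationSummary]:
    """Vectorized :func:`summarize_region` over a multi-region count table.

    Equivalent to tallying and summarizing each region separately; used for
    whole-experiment sweeps where per-region Python overhead matters.
    """
    valid = counts[counts["ref"].isin(BASES)].copy()
    rid = valid["region_id"].to_numpy()
    ref = valid["ref"].to_numpy()
    pos = valid["pos"].to_numpy()
    depth = valid["depth"].to_numpy(dtype=np.int64)
    base_counts = valid[list(BASES)].to_numpy(dtype=np.int64)
    ref_idx = pd.Categorical(valid["ref"], categories=list(BASES)).codes.astype(int)
    alt_counts = base_counts.copy()
    alt_counts[np.arange(len(valid)), ref_idx] = 0
    if min_alt_count > 1:
        alt_counts[alt_counts < min_alt_count] = 0
    alt_total = alt_counts.sum(axis=1)

    is_c = ref == "C"
    is_g = ref == "G"
    ct_events = np.where(is_c, alt_counts[:, 3], 0) + np.where(is_g, alt_counts[:, 0], 0)

    hot = np.zeros(len(valid), dtype=bool)
    if annotations:
        plus_minus = {
            rid_: _hotspot_position_sets(ann) for rid_, ann in annotations.items()
        }
        for i, (r, p) in enumerate(zip(rid, pos)):
            plus, minus = plus_minus.get(r, (set(), set()))
            if (is_c[i] and p in plus) or (is_g[i] and p in minus):
                hot[i] = True

    frame = pd.DataFrame(
        {
            "region_id": rid,
            "depth": depth,
            "alt_total": alt_total,
            "ct_events": ct_events,
            "depth_c": np.where(is_c, depth, 0),
            "depth_g": np.where(is_g, depth, 0),
            "alt_c": np.where(is_c, alt_total, 0),
            "alt_g": np.where(is_g, alt_total, 0),
            "depth_c_hot": np.where(is_c & hot, depth, 0),
            "depth_g_hot": np.where(is_g & hot, depth, 0),
            "alt_c_hot": np.where(is_c & hot, alt_total, 0),
            "alt_g_hot": np.where(is_g & hot, alt_total, 0),
        }
    )
    grouped = frame.groupby("region_id", sort=True).sum()
    out: dict[str, RegionMutationSummary] = {}
    for region_id, row in grouped.iterrows():
        out[str(region_id)] = RegionMutationSummary(
            region_id=str(region_id),
            total_mutations=int(row["alt_total"]),
            total_sequenced_length=int(row["depth"]),
            mutated_cytosines=int(row["alt_c"]),
            mutated_guanines=int(row["alt_g"]),
            seq_length_cytosines=int(row["depth_c"]),
            seq_length_guanines=int(row["depth_g"]),
            mutated_cytosines_hotspot=int(row["alt_c_hot"]),
            mutated_guanines_hotspot=int(row["alt_g_hot"]),
            seq_length_cytosines_hotspot=int(row["depth_c_hot"]),
            seq_length_guanines_hotspot=int(row["depth_g_hot"]),
            ct_transition_mutations=int(row["ct_events"]),
        )
    return out


def site_transition_frequencies(counts: pd.DataFrame) -> pd.Series:
    """Deaminated-C-frame transition frequency per C/G site.

    Returns a Series indexed by (region_id, pos): T calls / depth at
    reference C, A calls / depth at reference G (the C>T transition read in
    the minus frame).  Zero-depth sites report 0.
    """
    rows = counts[counts["ref"].isin(("C", "G"))]
    depth = rows["depth"].to_numpy(dtype=float)
    events = np.where(
        rows["ref"].to_numpy() == "C",
        rows["T"].to_numpy(dtype=float),
        rows["A"].to_numpy(dtype=float),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, events / depth, 0.0)
    index = pd.MultiIndex.from_arrays(
        [rows["region_id"], rows["pos"]], names=["region_id", "pos"]
    )
    return pd.Series(freq, index=index, name="ct_freq")


def per_base_profile(
    region: TargetRegion,
    case_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Control-adjusted per-position mutation-frequency track for one region.

    Per position: (sum of non-reference calls / depth) in the case minus the
    same in the control, floored at 0.  Control positions with zero depth
    contribute 0 and are flagged.
    """

    def _freqs(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        sub = counts[counts["region_id"] == region.region_id]
        sub = sub.set_index("pos").reindex(range(len(region)))
        depth = sub["depth"].fillna(0).to_numpy(dtype=float)
        base_counts = sub[list(BASES)].fillna(0).to_numpy(dtype=float)
        ref_idx = pd.Categorical(
            pd.Series(list(region.sequence)), categories=list(BASES)
        ).codes.astype(int)
        valid = ref_idx >= 0
        alt = base_counts.copy()
        alt[valid, ref_idx[valid]] = 0.0
        alt[~valid] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(depth > 0, alt.sum(axis=1) / depth, 0.0)
        return freq, depth

    case_freq, _ = _freqs(case_counts)
    ctrl_freq, ctrl_depth = _freqs(control_counts)
    adjusted = np.clip(case_freq - ctrl_freq, 0.0, None)
    return pd.DataFrame(
        {
            "region_id": region.region_id,
            "pos": np.arange(len(region)),
            "ref": list(region.sequence),
            "case_freq": case_freq,
            "control_freq": ctrl_freq,
            "adjusted_freq": adjusted,
            "control_zero_depth": ctrl_depth == 0,
        }
    )
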