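"""Synthetic targeted-capture data with the statistical structure of SHM.

The generator emulates the observables of a deep-sequencing mutation study
in germinal-center B cells: per-base base-call tallies over TSS-anchored
capture regions, for a panel of DNA-repair genotypes.  Mutant-allele
fractions are modeled directly as expected read fractions in a polyclonal
cell population (deamination is concentrated at hotspot motifs and scaled by
how much of it escapes faithful repair); stochasticity enters only through
Poisson sequencing depth and multinomial base calls.  Heterozygous germline
SNPs (allele fraction 0.5) and a uniform sequencing substitution error are
layered on top.

A separate generator produces gene-level feature tables in which mutability
is driven by a planted RNAPolII x Spt5 interaction, mirroring the structure
the tree predictor is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_regions import (
    PRESET_MOTIFS,
    MotifSpec,
    TargetRegion,
    annotate_hotspots,
)

__all__ = [
    "GenotypeModel",
    "GENOTYPES",
    "SimulationConfig",
    "FeatureEffect",
    "simulate_regions",
    "expected_site_frequencies",
    "simulate_counts",
    "simulate_dataset",
    "simulate_feature_table",
    "SimulatedDataset",
    "write_dataset",
]

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GenotypeModel:
    """Deamination/repair behaviour of one mouse genotype.

    ``escape_fraction`` is the proportion of AID deamination events that are
    not faithfully repaired and therefore surface as mutations;
    ``spectrum`` distributes escaped events at the deaminated C over the
    three substitution classes (keys ``C>T``, ``C>G``, ``C>A``; G sites are
    complement-mirrored); ``at_rate_scale`` converts escaped deaminations
    into collateral A/T-phase mutations spread over the region's A/T sites.
    """

    name: str
    escape_fraction: float
    spectrum: Mapping[str, float]
    at_rate_scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must lie in [0, 1]")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum weights must sum to 1, got {total}")
        if set(self.spectrum) - {"C>T", "C>G", "C>A"}:
            raise ValueError("spectrum keys must be C>T / C>G / C>A")


# Default genotype panel.  Escape fractions are qualitative: with both BER
# and MMR lost every deamination is replicated into a C>T transition; losing
# one pathway leaves the other to repair most lesions; with both (partially)
# intact only a small residue escapes.  Spectra follow the known division of
# labour: UNG creates abasic sites hence transversions, MSH2 drives the
# A/T-phase mutations.
GENOTYPES: dict[str, GenotypeModel] = {
    "Aicda_KO": GenotypeModel("Aicda_KO", 0.0, {"C>T": 1.0}, 0.0),
    "UngMsh2_DKO": GenotypeModel("UngMsh2_DKO", 1.0, {"C>T": 1.0}, 0.0),
    "Ung_KO": GenotypeModel(  # Ung-/- Msh2+/-
        "Ung_KO", 0.10, {"C>T": 0.90, "C>G": 0.05, "C>A": 0.05}, 0.5
    ),
    "Msh2_KO": GenotypeModel(  # Ung+/- Msh2-/-
        "Msh2_KO", 0.10, {"C>T": 0.50, "C>G": 0.30, "C>A": 0.20}, 0.0
    ),
    "DoubleHet": GenotypeModel(  # Ung+/- Msh2+/-
        "DoubleHet", 0.04, {"C>T": 0.70, "C>G": 0.20, "C>A": 0.10}, 0.3
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters of the synthetic capture experiment.

    Defaults emulate the study conditions: 500-bp TSS-proximal regions, a
    small fraction of genuinely AID-targeted regions, a baseline deamination
    mutant-allele fraction ``base_deamination`` at a non-hotspot C, hotspot
    boosts WRCY x10 and AGCTNT x25, deep coverage, a quality-filtered
    sequencing substitution error of 1e-4/base, and sparse heterozygous
    SNPs.  With ``hotspot_only`` deamination is restricted to cytosines
    inside the listed motifs (background cytosines get zero).
    """

    n_regions: int = 200
    region_length: int = 500
    gc_content: float = 0.5
    base_deamination: float = 2e-4
    motif_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"WRCY": 10.0, "AGCTNT": 25.0}
    )
    depth_mean: float = 500.0
    error_rate: float = 1e-4
    snp_rate: float = 1e-3
    target_fraction: float = 0.05
    hotspot_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_deamination", "error_rate", "snp_rate", "target_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    def motifs(self) -> list[MotifSpec]:
        return [PRESET_MOTIFS[name] for name in self.motif_multipliers]


@dataclass(frozen=True)
class FeatureEffect:
    """Planted effect for the gene feature table.

    ``P(target) = logistic(baseline_logit + interaction_logit *
    1[polII > q and spt5 > q])`` with ``q`` the empirical
    ``quantile_threshold`` quantile of each density.
    """

    baseline_logit: float = -3.0
    interaction_logit: float = 4.2
    quantile_threshold: float = 0.75


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def simulate_regions(
    config: SimulationConfig,
) -> tuple[list[TargetRegion], dict[str, dict[int, str]]]:
    """Random capture regions plus a heterozygous-SNP mask.

    Returns ``(regions, snps)`` where ``snps[region_id]`` maps region-local
    position to the germline alternate base.  Deterministic under
    ``config.seed`` through a per-region stream split.
    """
    probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    regions: list[TargetRegion] = []
    snps: dict[str, dict[int, str]] = {}
    for i in range(config.n_regions):
        rng = _child_rng(config.seed, 0, i)
        idx = rng.choice(4, size=config.region_length, p=probs)
        seq = _BASE_BYTES[idx].tobytes().decode()
        region_id = f"r{i:04d}"
        regions.append(
            TargetRegion(
                region_id=region_id,
                gene=f"gene{i:04d}",
                chrom=f"chrS{i:04d}",
                start=0,
                end=config.region_length,
                sequence=seq,
            )
        )
        snp_pos = np.flatnonzero(rng.random(config.region_length) < config.snp_rate)
        region_snps: dict[int, str] = {}
        for pos in snp_pos:
            alts = [b for b in BASES if b != seq[pos]]
            region_snps[int(pos)] = alts[rng.integers(len(alts))]
        snps[region_id] = region_snps
    return regions, snps


def _expected_fracs(
    region: TargetRegion,
    genotype: GenotypeModel,
    config: SimulationConfig,
    hotspots: Mapping[int, set[tuple[str, str]]],
) -> np.ndarray:
    """(length, 4) expected mutant-allele fractions, columns A/C/G/T."""
    length = len(region)
    seq = np.frombuffer(region.sequence.encode(), dtype="S1")
    frac = np.zeros((length, 4))
    if genotype.escape_fraction == 0.0:
        return frac

    c_mask = seq == b"C"
    g_mask = seq == b"G"
    mult = np.zeros(length) if config.hotspot_only else np.ones(length)
    for pos, members in hotspots.items():
        frame = "+" if c_mask[pos] else ("-" if g_mask[pos] else None)
        best = mult[pos]
        for motif_name, strand in members:
            if strand == frame and motif_name in config.motif_multipliers:
                best = max(best, config.motif_multipliers[motif_name])
        mult[pos] = best
    deam = np.where(c_mask | g_mask, config.base_deamination * mult, 0.0)
    escaped = deam * genotype.escape_fraction

    for cls, weight in genotype.spectrum.items():
        alt_c = cls[2]
        frac[c_mask, _BASE_INDEX[alt_c]] += escaped[c_mask] * weight
        frac[g_mask, _BASE_INDEX[_COMPLEMENT[alt_c]]] += escaped[g_mask] * weight

    if genotype.at_rate_scale > 0:
        at_mask = (seq == b"A") | (seq == b"T")
        n_at = int(at_mask.sum())
        if n_at:
            per_site = genotype.at_rate_scale * escaped.sum() / n_at
            frac[at_mask] += per_site / 3.0
            # no mass on the reference base itself
            frac[seq == b"A", _BASE_INDEX["A"]] = 0.0
            frac[seq == b"T", _BASE_INDEX["T"]] = 0.0
    return frac


def expected_site_frequencies(
    region: TargetRegion,
    genotype: GenotypeModel,
    config: SimulationConfig,
    hotspots: Mapping[int, set[tuple[str, str]]],
) -> pd.DataFrame:
    """Ground-truth expected mutant-allele fractions per site and class.

    At each C (plus frame) or G (minus frame) the deamination fraction is
    ``base_deamination`` times the largest multiplier among the motifs whose
    instance covers the site in the matching frame (1 if none; 0 if none and
    ``hotspot_only``).  Per-class expected fractions multiply in the
    genotype's escape fraction and spectrum weights; G-site classes are the
    complement-mirrored C classes.  Collateral A/T mass (``at_rate_scale``
    times the region's total escaped deamination) is spread uniformly over
    A/T sites and split evenly across the three alternate bases.
    """
    frac = _expected_fracs(region, genotype, config, hotspots)
    return pd.DataFrame(
        {
            "region_id": region.region_id,
            "pos": np.arange(len(region)),
            "ref": list(region.sequence),
            "frac_A": frac[:, 0],
            "frac_C": frac[:, 1],
            "frac_G": frac[:, 2],
            "frac_T": frac[:, 3],
        }
    )


def _simulate_counts_arrays(
    sequence: str,
    frac: np.ndarray,
    snp_mask: Mapping[int, str],
    depth_mean: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth and multinomial base-call counts for one region."""
    length = len(sequence)
    seq = np.frombuffer(sequence.encode(), dtype="S1")
    probs = frac.copy()
    ref_idx = np.full(length, -1)
    for base, j in _BASE_INDEX.items():
        ref_idx[seq == base.encode()] = j
    valid = ref_idx >= 0
    nonref = np.ones((length, 4), dtype=bool)
    nonref[valid, ref_idx[valid]] = False
    probs[nonref] += error_rate / 3.0
    for pos, alt in snp_mask.items():
        probs[pos, _BASE_INDEX[alt]] += 0.5
    rest = 1.0 - probs.sum(axis=1)
    probs[valid, ref_idx[valid]] += rest[valid]
    if (~valid).any():  # 'N' reference: spread leftover mass evenly
        probs[~valid] += rest[~valid, None] / 4.0
    depth = rng.poisson(depth_mean, size=length)
    counts = rng.multinomial(depth, probs)
    return depth, counts


def _counts_frame(
    region: TargetRegion, depth: np.ndarray, counts: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": region.region_id,
            "pos": np.arange(len(region)),
            "ref": list(region.sequence),
            "depth": depth,
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
        }
    )


def simulate_counts(
    region: TargetRegion,
    truth: pd.DataFrame,
    snp_mask: Mapping[int, str],
    depth_mean: float,
    error_rate: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Per-base base-call tallies for one region.

    Depth is Poisson(``depth_mean``); given depth, base calls are
    multinomial with probabilities = truth fractions + ``error_rate/3`` per
    non-reference base, plus 0.5 toward the germline alternate at SNP
    positions; all remaining mass goes to the reference base.  Counts over
    the four bases sum to depth at every site.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if len(truth) != len(region):
        raise ValueError("truth does not cover the region")
    frac = truth[["frac_A", "frac_C", "frac_G", "frac_T"]].to_numpy()
    depth, counts = _simulate_counts_arrays(
        region.sequence, frac, snp_mask, depth_mean, error_rate, rng
    )
    return _counts_frame(region, depth, counts)


@dataclass
class SimulatedDataset:
    """One synthetic capture experiment across a genotype panel."""

    config: SimulationConfig
    regions: list[TargetRegion]
    snps: dict[str, dict[int, str]]
    target_ids: set[str]
    annotations: dict[str, dict[int, set[tuple[str, str]]]]
    truth: dict[str, pd.DataFrame]  # genotype -> concatenated SiteTruth
    counts: dict[str, pd.DataFrame]  # genotype -> concatenated SiteCounts


def simulate_dataset(
    config: SimulationConfig,
    genotypes: Sequence[str | GenotypeModel] = ("UngMsh2_DKO", "Aicda_KO"),
    replicate: int = 0,
    keep_truth: bool = True,
) -> SimulatedDataset:
    """Full experiment: regions, SNPs, per-genotype truth and count tables.

    A ``target_fraction`` subset of regions is planted as genuine AID
    targets; non-target regions have zero deamination in every genotype
    (their counts still carry sequencing error and SNPs).  All randomness
    derives from ``config.seed`` through a per-region/per-genotype stream
    split, so any genotype subset reproduces identically; ``replicate``
    indexes independent count draws over the same regions, SNPs and truth
    (an independent mouse cohort).
    """
    models = [GENOTYPES[g] if isinstance(g, str) else g for g in genotypes]
    regions, snps = simulate_regions(config)
    rng_targets = _child_rng(config.seed, 1)
    n_targets = int(round(config.target_fraction * len(regions)))
    target_idx = rng_targets.choice(len(regions), size=n_targets, replace=False)
    target_ids = {regions[i].region_id for i in sorted(target_idx)}

    motifs = config.motifs()
    annotations = {r.region_id: annotate_hotspots(r, motifs) for r in regions}

    null_model = GENOTYPES["Aicda_KO"]
    rid_col = np.concatenate(
        [np.repeat(r.region_id, len(r)) for r in regions]
    )
    pos_col = np.concatenate([np.arange(len(r)) for r in regions])
    ref_col = np.frombuffer(
        "".join(r.sequence for r in regions).encode(), dtype="S1"
    ).astype("U1")
    truth_acc: dict[str, list[np.ndarray]] = {m.name: [] for m in models}
    depth_acc: dict[str, list[np.ndarray]] = {m.name: [] for m in models}
    count_acc: dict[str, list[np.ndarray]] = {m.name: [] for m in models}
    for i, region in enumerate(regions):
        ann = annotations[region.region_id]
        for gi, model in enumerate(models):
            effective = model if region.region_id in target_ids else null_model
            frac = _expected_fracs(region, effective, config, ann)
            rng = _child_rng(config.seed, 2, i, gi, replicate)
            depth, counts = _simulate_counts_arrays(
                region.sequence, frac, snps[region.region_id],
                config.depth_mean, config.error_rate, rng,
            )
            depth_acc[model.name].append(depth)
            count_acc[model.name].append(counts)
            if keep_truth:
                truth_acc[model.name].append(frac)
    counts = {}
    truth = {}
    for model in models:
        g = model.name
        stacked = np.concatenate(count_acc[g])
        counts[g] = pd.DataFrame(
            {
                "region_id": rid_col,
                "pos": pos_col,
                "ref": ref_col,
                "depth": np.concatenate(depth_acc[g]),
                "A": stacked[:, 0],
                "C": stacked[:, 1],
                "G": stacked[:, 2],
                "T": stacked[:, 3],
            }
        )
        if keep_truth:
            frac_all = np.concatenate(truth_acc[g])
            truth[g] = pd.DataFrame(
                {
                    "region_id": rid_col,
                    "pos": pos_col,
                    "ref": ref_col,
                    "frac_A": frac_all[:, 0],
                    "frac_C": frac_all[:, 1],
                    "frac_G": frac_all[:, 2],
                    "frac_T": frac_all[:, 3],
                }
            )
    return SimulatedDataset(config, regions, snps, target_ids, annotations, truth, counts)


def simulate_feature_table(
    n_genes: int,
    effect: FeatureEffect = FeatureEffect(),
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level feature table with a planted PolII x Spt5 mutability rule.

    Continuous features are lognormal around a shared latent activity
    (coupling 0.5, unit noise); binary chromatin/regulatory marks are
    Bernoulli with activity-linked probabilities.  The true label is drawn
    from the logistic model documented on :class:`FeatureEffect`.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    rng = np.random.default_rng(seed)
    activity = rng.normal(size=n_genes)

    def lognormal_feature(scale: float = 1.0) -> np.ndarray:
        return scale * np.exp(0.5 * activity + rng.normal(size=n_genes))

    table = pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n_genes)],
            "expression_tpm": lognormal_feature(10.0),
            "transcription_rate": lognormal_feature(1.0),
            "polII_density": lognormal_feature(1.0),
            "spt5_density": lognormal_feature(1.0),
        }
    )
    link = 1.0 / (1.0 + np.exp(-0.5 * activity))
    for mark in ("med12", "h3k4me1", "h3k36me3", "h3k79me2", "superenhancer", "convt"):
        table[mark] = (rng.random(n_genes) < link).astype(int)
    # background (AID-null) frequency: log10-normal around 1e-4
    table["background_freq"] = 10.0 ** rng.normal(-4.0, 0.3, size=n_genes)

    q = effect.quantile_threshold
    high = (
        (table["polII_density"] > table["polII_density"].quantile(q))
        & (table["spt5_density"] > table["spt5_density"].quantile(q))
    ).to_numpy()
    logit = effect.baseline_logit + effect.interaction_logit * high
    p_target = 1.0 / (1.0 + np.exp(-logit))
    table["label"] = np.where(rng.random(n_genes) < p_target, "target", "nontarget")
    return table


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write regions.fasta, regions.bed, snps.bed, counts_<genotype>.tsv,
    truth_<genotype>.tsv and the planted-target list to ``outdir``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(r.sequence), id=r.chrom, description=r.region_id)
        for r in dataset.regions
    ]
    SeqIO.write(records, str(outdir / "regions.fasta"), "fasta")
    with open(outdir / "regions.bed", "w") as handle:
        for r in dataset.regions:
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{r.gene}\n")
    with open(outdir / "snps.bed", "w") as handle:
        for r in dataset.regions:
            for pos, alt in sorted(dataset.snps[r.region_id].items()):
                handle.write(f"{r.chrom}\t{r.start + pos}\t{r.start + pos + 1}\t{alt}\n")
    for genotype, counts in dataset.counts.items():
        counts.to_csv(outdir / f"counts_{genotype}.tsv", sep="\t", index=False)
    for genotype, truth in dataset.truth.items():
        truth.to_csv(outdir / f"truth_{genotype}.tsv", sep="\t", index=False)
    with open(outdir / "targets_truth.txt", "w") as handle:
        for rid in sorted(dataset.target_ids):
            handle.write(rid + "\n")
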