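"""Target regions and strand-aware AID hotspot motif scanning.

AID deaminates cytosines, so hotspot motifs (WRC, WRCY, AGCTNT, ...) are
defined in the *deaminated-C frame*: a match on the plus strand marks a C,
while a match of the reverse-complemented pattern marks a G whose paired C
on the minus strand is the deaminated base.  All coordinates are 0-based
half-open; reported hotspot positions are plus-strand indices of the
deaminated base (a C for '+' instances, a G for '-' instances).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pyfaidx import Fasta

__all__ = [
    "TargetRegion",
    "MotifSpec",
    "HotspotInstance",
    "PRESET_MOTIFS",
    "WRCY_VARIANTS",
    "revcomp",
    "load_regions",
    "scan_motif",
    "annotate_hotspots",
    "write_hotspot_bed",
]

# IUPAC degenerate nucleotide codes.  An 'N' in a *sequence* is treated as an
# unknown base: it is matched only by the motif letter 'N', never by A/C/G/T
# or any other degenerate class.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTWRYSKMBDHVN", "TGCAWYRSMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (uppercase)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetRegion:
    """A captured genomic interval with its plus-strand sequence."""

    region_id: str
    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"region {self.region_id}: sequence length {len(self.sequence)} "
                f"!= end - start = {self.end - self.start}"
            )
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"region {self.region_id}: non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC hotspot motif with the deaminated C at a fixed offset.

    ``deaminated_index`` is the 0-based offset of the deaminated cytosine
    within the motif; the motif letter there must be a literal 'C'.
    """

    name: str
    iupac: str
    deaminated_index: int

    def __post_init__(self) -> None:
        if len(self.iupac) < 1:
            raise ValueError("empty motif")
        bad = sorted(set(self.iupac) - set(IUPAC_SETS))
        if bad:
            raise ValueError(f"motif {self.name}: letters outside IUPAC alphabet: {bad}")
        if not 0 <= self.deaminated_index < len(self.iupac):
            raise ValueError(f"motif {self.name}: deaminated_index out of range")
        if self.iupac[self.deaminated_index] != "C":
            raise ValueError(
                f"motif {self.name}: letter at deaminated_index must be 'C', "
                f"got {self.iupac[self.deaminated_index]!r}"
            )

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class HotspotInstance:
    """One strand-resolved motif match.

    ``position`` indexes the deaminated base on the plus strand: a C for
    strand '+', a G for strand '-' (the deaminated C lies on the minus
    strand).
    """

    region_id: str
    position: int
    strand: str  # '+' or '-'
    motif_name: str


# The eight concrete WRCY four-mers (W in {A,T} x R in {A,G} x Y in {C,T}).
WRCY_VARIANTS: tuple[str, ...] = (
    "AACT", "AGCT", "TACT", "TGCT", "AACC", "AGCC", "TACC", "TGCC",
)

PRESET_MOTIFS: dict[str, MotifSpec] = {
    "WRC": MotifSpec("WRC", "WRC", 2),
    "WRCY": MotifSpec("WRCY", "WRCY", 2),
    "AGCTNT": MotifSpec("AGCTNT", "AGCTNT", 2),
    "AGCTNV": MotifSpec("AGCTNV", "AGCTNV", 2),
}
for _v in WRCY_VARIANTS:
    PRESET_MOTIFS[_v] = MotifSpec(_v, _v, 2)


def load_regions(bed_path: str | Path, fasta_path: str | Path) -> list[TargetRegion]:
    """Read capture regions from a BED file and slice their sequences.

    The BED name column (4th) is the region id; an optional 5th column is
    ignored and an optional 6th-column gene name is used when present,
    otherwise the gene defaults to the region id.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    regions: list[TargetRegion] = []
    with open(bed_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{bed_path}:{lineno}: BED line needs >=4 columns")
            chrom, start_s, end_s, region_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if chrom not in fasta:
                raise KeyError(f"{bed_path}:{lineno}: contig {chrom!r} not in FASTA")
            contig_len = len(fasta[chrom])
            if start < 0 or end > contig_len or end <= start:
                raise ValueError(
                    f"{bed_path}:{lineno}: interval [{start},{end}) outside "
                    f"contig {chrom} (length {contig_len})"
                )
            gene = fields[5] if len(fields) >= 6 and fields[5] not in "+-" else region_id
            seq = str(fasta[chrom][start:end]).upper()
            regions.append(TargetRegion(region_id, gene, chrom, start, end, seq))
    return regions


def _motif_regex(iupac: str) -> re.Pattern[str]:
    # Lookahead so overlapping and nested matches are all reported.
    classes = "".join(f"[{''.join(sorted(IUPAC_SETS[c]))}]" for c in iupac)
    return re.compile(f"(?=({classes}))")


def scan_motif(
    sequence: str, motif: MotifSpec, region_id: str = ""
) -> list[HotspotInstance]:
    """All strand-resolved matches of ``motif`` in ``sequence``.

    Plus-strand matches report the deaminated C directly; minus-strand
    matches are located by scanning the reverse complement of the pattern on
    the plus strand, and report the plus-strand G paired with the deaminated
    minus-strand C.
    """
    length = len(motif)
    out: list[HotspotInstance] = []
    for m in _motif_regex(motif.iupac).finditer(sequence):
        out.append(
            HotspotInstance(region_id, m.start() + motif.deaminated_index, "+", motif.name)
        )
    rc_pattern = revcomp(motif.iupac)
    offset = length - 1 - motif.deaminated_index
    for m in _motif_regex(rc_pattern).finditer(sequence):
        out.append(HotspotInstance(region_id, m.start() + offset, "-", motif.name))
    out.sort(key=lambda h: (h.position, h.strand))
    return out


def annotate_hotspots(
    region: TargetRegion, motifs: Iterable[MotifSpec]
) -> dict[int, set[tuple[str, str]]]:
    """Union of motif matches keyed by position.

    Returns ``{position: {(motif_name, strand), ...}}``; a base inside
    several instances appears once with all its memberships.
    """
    annotation: dict[int, set[tuple[str, str]]] = {}
    for motif in motifs:
        for inst in scan_motif(region.sequence, motif, region.region_id):
            annotation.setdefault(inst.position, set()).add((inst.motif_name, inst.strand))
    return annotation


def write_hotspot_bed(
    regions: Iterable[TargetRegion],
    annotations: Mapping[str, Mapping[int, set[tuple[str, str]]]],
    path: str | Path,
) -> None:
    """Export hotspot annotations as BED with name ``motif|strand``."""
    with open(path, "w") as handle:
        for region in regions:
            ann = annotations.get(region.region_id, {})
            for pos in sorted(ann):
                for motif_name, strand in sorted(ann[pos]):
                    handle.write(
                        f"{region.chrom}\t{region.start + pos}\t{region.start + pos + 1}"
                        f"\t{motif_name}|{strand}\t0\t{strand}\n"
                    )
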