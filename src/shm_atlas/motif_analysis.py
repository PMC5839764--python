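"""Sequence context of mutated cytosines and hotspot motif mutability.

All context analysis happens in the deaminated-C frame: windows around
mutated guanines (deaminated C on the minus strand) are reverse-complemented
so the mutated cytosine is always central and read 5'->3'.  Composition and
per-position enrichment mirror a logo analysis: base percentages per
position, plus a one-tailed Fisher test of each (position, base) against the
context of all cytosines in the analyzed regions, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_regions import (
    PRESET_MOTIFS,
    WRCY_VARIANTS,
    MotifSpec,
    TargetRegion,
    revcomp,
    scan_motif,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContextWindow",
    "extract_contexts",
    "all_cytosine_contexts",
    "position_composition",
    "position_enrichment",
    "motif_mutability",
    "mann_whitney_two_tailed",
    "random_motifs",
]


@dataclass(frozen=True)
class ContextWindow:
    """A deaminated-C-frame flank window around one mutated cytosine."""

    region_id: str
    position: int
    c_frame_strand: str
    context: str  # length 2w + 1, middle base 'C'
    center_freq: float


def _window(
    region: TargetRegion, pos: int, strand: str, w: int, freq: float
) -> ContextWindow | None:
    if pos - w < 0 or pos + w + 1 > len(region):
        return None
    ctx = region.sequence[pos - w : pos + w + 1]
    if strand == "-":
        ctx = revcomp(ctx)
    return ContextWindow(region.region_id, pos, strand, ctx, freq)


def extract_contexts(
    site_freqs: pd.Series,
    regions: Mapping[str, TargetRegion] | Iterable[TargetRegion],
    threshold: float = 4e-3,
    w: int = 5,
) -> list[ContextWindow]:
    """Context windows of mutated cytosines above the frequency threshold.

    ``site_freqs`` is a control-adjusted deaminated-C-frame transition
    frequency Series indexed by (region_id, pos) over C/G sites.  Sites with
    frequency >= ``threshold`` are emitted as (2w+1)-mers; windows truncated
    by a region edge are dropped (logged).
    """
    region_map = (
        regions if isinstance(regions, Mapping) else {r.region_id: r for r in regions}
    )
    contexts: list[ContextWindow] = []
    dropped = 0
    selected = site_freqs[site_freqs >= threshold]
    for (region_id, pos), freq in selected.items():
        region = region_map[region_id]
        base = region.sequence[pos]
        if base not in ("C", "G"):
            continue
        strand = "+" if base == "C" else "-"
        window = _window(region, int(pos), strand, w, float(freq))
        if window is None:
            dropped += 1
            continue
        contexts.append(window)
    if dropped:
        logger.info("extract_contexts: dropped %d edge-truncated windows", dropped)
    return contexts


def all_cytosine_contexts(
    regions: Mapping[str, TargetRegion] | Iterable[TargetRegion], w: int = 5
) -> list[ContextWindow]:
    """Background: context of every cytosine in both frames (freq 0)."""
    region_map = (
        regions if isinstance(regions, Mapping) else {r.region_id: r for r in regions}
    )
    contexts: list[ContextWindow] = []
    for region in region_map.values():
        for pos, base in enumerate(region.sequence):
            if base == "C":
                window = _window(region, pos, "+", w, 0.0)
            elif base == "G":
                window = _window(region, pos, "-", w, 0.0)
            else:
                continue
            if window is not None:
                contexts.append(window)
    return contexts


def position_composition(contexts: Sequence[ContextWindow]) -> pd.DataFrame:
    """Base percentages per window position (logo matrix).

    Rows are positions -w..+w (0 = the mutated C), columns A/C/G/T; each row
    sums to 100 over the non-N calls at that position.
    """
    if not contexts:
        raise ValueError("no contexts")
    width = len(contexts[0].context)
    w = width // 2
    matrix = np.zeros((width, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for ctx in contexts:
        if len(ctx.context) != width:
            raise ValueError("mixed window widths")
        for i, base in enumerate(ctx.context):
            if base in base_idx:
                matrix[i, base_idx[base]] += 1
    totals = matrix.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    pct = 100.0 * matrix / totals
    return pd.DataFrame(
        pct, index=pd.Index(range(-w, w + 1), name="position"), columns=list("ACGT")
    )


def position_enrichment(
    foreground: Sequence[ContextWindow],
    background: Sequence[ContextWindow],
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-(position, base) one-tailed Fisher enrichment vs background.

    ``background`` must be the contexts of all cytosines in the analyzed
    regions (both frames) and at least as large as the foreground.  For each
    non-center position and base, tests [fg with base, fg without; bg with
    base, bg without] one-tailed for enrichment and Bonferroni-adjusts over
    the 4 * 2w tests.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if len(background) < len(foreground):
        raise ValueError("background smaller than foreground")
    width = len(foreground[0].context)
    w = width // 2
    n_tests = 4 * 2 * w
    rows = []
    for offset in range(-w, w + 1):
        if offset == 0:
            continue
        i = offset + w
        fg_bases = [ctx.context[i] for ctx in foreground]
        bg_bases = [ctx.context[i] for ctx in background]
        n_fg, n_bg = len(fg_bases), len(bg_bases)
        for base in "ACGT":
            fg_with = sum(1 for b in fg_bases if b == base)
            bg_with = sum(1 for b in bg_bases if b == base)
            p = float(
                stats.hypergeom.sf(fg_with - 1, n_fg + n_bg, fg_with + bg_with, n_fg)
            )
            rows.append({"position": offset, "base": base, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * n_tests, 1.0)
    out["significant"] = out["p_adj"] <= alpha
    return out


def motif_mutability(
    site_freqs: pd.Series,
    regions: Mapping[str, TargetRegion] | Iterable[TargetRegion],
    motifs: Sequence[MotifSpec],
) -> pd.DataFrame:
    """Per-motif site frequency vectors and means, ranked by mean.

    Every strand-resolved instance of each motif contributes its site's
    adjusted frequency (0 when the site is absent from ``site_freqs``).
    Motifs without instances report ``n_sites`` 0 and a NaN mean (flagged in
    the ``undefined`` column).
    """
    region_map = (
        regions if isinstance(regions, Mapping) else {r.region_id: r for r in regions}
    )
    freq_map = site_freqs.to_dict()
    rows = []
    for motif in motifs:
        values: list[float] = []
        for region in region_map.values():
            for inst in scan_motif(region.sequence, motif, region.region_id):
                values.append(float(freq_map.get((inst.region_id, inst.position), 0.0)))
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                "motif_name": motif.name,
                "n_sites": arr.size,
                "mean_freq": float(arr.mean()) if arr.size else np.nan,
                "site_freqs": values,
                "undefined": arr.size == 0,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        "mean_freq", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with midrank tie handling."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney_two_tailed(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    For combined sample size <= 12 the p-value is exact: all label
    reassignments are enumerated (midranks, so ties are handled) and the
    two-tailed p is the fraction of assignments whose U deviates from the
    null mean n1*n2/2 at least as much as observed.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size == 0 or y_arr.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x_arr.size, y_arr.size
    u_obs = _u_statistic(x_arr, y_arr)
    if n1 + n2 <= 12:
        combined = np.concatenate([x_arr, y_arr])
        ranks = stats.rankdata(combined)
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        hits = 0
        total = comb(n1 + n2, n1)
        base = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - base
            if abs(u_perm - center) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(
        x_arr, y_arr, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(res.pvalue)


def random_motifs(k: int, length: int = 4, seed: int = 0) -> list[MotifSpec]:
    """Random concrete 4-mer motifs with the deaminated C fixed at index 2.

    Controls for hotspot ranking: drawn without replacement from all
    ACGT 4-mers with C at index 2, excluding the WRCY variants and motifs
    with the AGCT core.  Deterministic under ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if length != 4:
        raise ValueError("only length-4 random motifs are supported")
    wrcy = set(WRCY_VARIANTS)
    candidates = []
    for b0 in "ACGT":
        for b1 in "ACGT":
            for b3 in "ACGT":
                motif = f"{b0}{b1}C{b3}"
                if motif in wrcy or motif == "AGCT":
                    continue
                candidates.append(motif)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} available motifs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return [MotifSpec(candidates[i], candidates[i], 2) for i in sorted(chosen)]
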