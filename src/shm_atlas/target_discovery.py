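"""Calling AID targets and downstream gene-level statistics.

A region is an AID target when it accumulates significantly more C>T/G>A
transition events in the repair-deficient case genotype than in the AID-null
control: a one-tailed Fisher exact test on read-level events versus
depth-weighted C/G exposure, Benjamini-Hochberg-adjusted across regions,
called at q <= alpha.  Gene-level helpers classify mutability tiers and test
gene-set overlaps (e.g. against lymphoma gene lists) with a two-tailed
Fisher test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mutation_profiling import RegionMutationSummary

logger = logging.getLogger(__name__)

__all__ = [
    "RegionTestResult",
    "fisher_one_tailed",
    "benjamini_hochberg",
    "bonferroni",
    "call_targets",
    "compare_genotypes",
    "classify_mutability",
    "gene_set_enrichment",
]


@dataclass(frozen=True)
class RegionTestResult:
    region_id: str
    m_case: int
    n_case: int
    m_ctrl: int
    n_ctrl: int
    p_value: float
    q_value: float
    is_target: bool


def fisher_one_tailed(m_case: int, n_case: int, m_ctrl: int, n_ctrl: int) -> float:
    """Upper-tail Fisher exact p for case enrichment.

    The probability, under the hypergeometric null fixing all margins, of
    observing at least ``m_case`` events among the ``n_case`` case bases
    given ``m_case + m_ctrl`` events over ``n_case + n_ctrl`` bases.
    """
    if min(m_case, n_case, m_ctrl, n_ctrl) < 0:
        raise ValueError("negative contingency entries")
    if n_case == 0 and n_ctrl == 0:
        raise ValueError("empty contingency")
    if m_case > n_case or m_ctrl > n_ctrl:
        raise ValueError("events exceed exposure")
    total = n_case + n_ctrl
    successes = m_case + m_ctrl
    return float(stats.hypergeom.sf(m_case - 1, total, successes, n_case))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: ``min(p * m, 1)`` elementwise."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def call_targets(
    case_summaries: Mapping[str, RegionMutationSummary],
    ctrl_summaries: Mapping[str, RegionMutationSummary],
    alpha: float = 0.05,
) -> list[RegionTestResult]:
    """Per-region one-tailed Fisher versus the AID-null control, BH-adjusted.

    Events are C>T/G>A transition calls; exposure is the depth-weighted C/G
    sequenced length.  Regions present in only one genotype are excluded
    with a warning.
    """
    shared = sorted(set(case_summaries) & set(ctrl_summaries))
    skipped = (set(case_summaries) | set(ctrl_summaries)) - set(shared)
    if skipped:
        logger.warning(
            "call_targets: %d regions present in only one genotype, excluded",
            len(skipped),
        )
    if not shared:
        return []
    m_case = np.array(
        [case_summaries[r].ct_transition_mutations for r in shared], dtype=np.int64
    )
    n_case = np.array(
        [
            case_summaries[r].seq_length_cytosines + case_summaries[r].seq_length_guanines
            for r in shared
        ],
        dtype=np.int64,
    )
    m_ctrl = np.array(
        [ctrl_summaries[r].ct_transition_mutations for r in shared], dtype=np.int64
    )
    n_ctrl = np.array(
        [
            ctrl_summaries[r].seq_length_cytosines + ctrl_summaries[r].seq_length_guanines
            for r in shared
        ],
        dtype=np.int64,
    )
    p = stats.hypergeom.sf(m_case - 1, n_case + n_ctrl, m_case + m_ctrl, n_case)
    p = np.minimum(np.asarray(p, dtype=float), 1.0)
    q = benjamini_hochberg(p)
    return [
        RegionTestResult(
            region_id=r,
            m_case=int(m_case[i]),
            n_case=int(n_case[i]),
            m_ctrl=int(m_ctrl[i]),
            n_ctrl=int(n_ctrl[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            is_target=bool(q[i] <= alpha),
        )
        for i, r in enumerate(shared)
    ]


def compare_genotypes(
    replicate_summaries: Mapping[str, Sequence[Mapping[str, RegionMutationSummary]]],
    ctrl_summaries: Mapping[str, RegionMutationSummary],
    alpha: float = 0.05,
    regions: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Genotype x region adjusted-frequency matrix plus per-region Welch tests.

    For each genotype the AID-null control total frequency is subtracted
    from each replicate's total frequency (floored at 0); the matrix holds
    the replicate mean.  With >=2 replicates per genotype, a two-tailed
    Student t test (pooled variance; replicate counts are tiny, so pooling
    is what keeps the test usable) compares every genotype pair per region;
    otherwise tests are skipped with a warning.
    """
    if regions is None:
        region_set: set[str] = set()
        for reps in replicate_summaries.values():
            for rep in reps:
                region_set.update(rep)
        regions = sorted(region_set & set(ctrl_summaries))
    adjusted: dict[str, dict[str, np.ndarray]] = {}
    for genotype, reps in replicate_summaries.items():
        per_region: dict[str, np.ndarray] = {}
        for region_id in regions:
            ctrl = ctrl_summaries[region_id].total_freq
            values = [
                max(rep[region_id].total_freq - ctrl, 0.0)
                for rep in reps
                if region_id in rep
            ]
            per_region[region_id] = np.asarray(values, dtype=float)
        adjusted[genotype] = per_region
    matrix = pd.DataFrame(
        {
            genotype: [
                per_region[r].mean() if per_region[r].size else np.nan for r in regions
            ]
            for genotype, per_region in adjusted.items()
        },
        index=pd.Index(regions, name="region_id"),
    )

    testable = all(len(reps) >= 2 for reps in replicate_summaries.values())
    if not testable:
        logger.warning("compare_genotypes: <2 replicates for some genotype; tests skipped")
        return matrix, None
    rows = []
    for g1, g2 in combinations(sorted(replicate_summaries), 2):
        for region_id in regions:
            x = adjusted[g1][region_id]
            y = adjusted[g2][region_id]
            if x.size < 2 or y.size < 2:
                continue
            if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
                p_val = 1.0
            else:
                p_val = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
                if np.isnan(p_val):
                    p_val = 1.0
            rows.append(
                {
                    "region_id": region_id,
                    "genotype_a": g1,
                    "genotype_b": g2,
                    "mean_a": float(x.mean()),
                    "mean_b": float(y.mean()),
                    "p_value": p_val,
                    "significant": p_val <= alpha,
                }
            )
    return matrix, pd.DataFrame(rows)


def classify_mutability(
    gene_ct_freqs: Mapping[str, float],
    target_flags: Mapping[str, bool],
    highly_threshold: float = 3e-4,
    top_fraction: float = 0.2,
) -> pd.DataFrame:
    """Three mutability tiers: highly mutated, mutated, nonmutated.

    Highly mutated genes are targets in the top ``top_fraction`` of target
    C>T frequencies whose frequency also exceeds ``highly_threshold``; the
    remaining targets are "mutated"; non-targets are "nonmutated".
    """
    genes = sorted(gene_ct_freqs)
    targets = [g for g in genes if target_flags.get(g, False)]
    k = int(np.ceil(top_fraction * len(targets)))
    top = set(
        sorted(targets, key=lambda g: (-gene_ct_freqs[g], g))[:k]
    )
    rows = []
    for gene in genes:
        freq = gene_ct_freqs[gene]
        if gene in targets and gene in top and freq > highly_threshold:
            tier = "highly_mutated"
        elif gene in targets:
            tier = "mutated"
        else:
            tier = "nonmutated"
        rows.append({"gene": gene, "class": tier, "ct_freq": freq})
    return pd.DataFrame(rows)


def gene_set_enrichment(
    universe: Sequence[str],
    target_flags: Mapping[str, bool],
    set_flags: Mapping[str, bool],
) -> dict[str, float]:
    """Overlap of the target set with an annotated gene set.

    Builds the 2x2 table [targets in set, targets not in set; nontargets in
    set, nontargets not in set] over ``universe`` and returns the two
    percentages (rounded to 0.1), the odds ratio and the exact two-tailed
    Fisher p.
    """
    if not universe:
        raise ValueError("empty universe")
    in_t_in_s = sum(1 for g in universe if target_flags.get(g) and set_flags.get(g))
    in_t_out_s = sum(1 for g in universe if target_flags.get(g) and not set_flags.get(g))
    out_t_in_s = sum(1 for g in universe if not target_flags.get(g) and set_flags.get(g))
    out_t_out_s = sum(
        1 for g in universe if not target_flags.get(g) and not set_flags.get(g)
    )
    n_targets = in_t_in_s + in_t_out_s
    n_nontargets = out_t_in_s + out_t_out_s
    table = [[in_t_in_s, in_t_out_s], [out_t_in_s, out_t_out_s]]
    odds_ratio, p_value = stats.fisher_exact(table, alternative="two-sided")
    return {
        "proportion_in_targets": round(100.0 * in_t_in_s / n_targets, 1)
        if n_targets
        else 0.0,
        "proportion_in_nontargets": round(100.0 * out_t_in_s / n_nontargets, 1)
        if n_nontargets
        else 0.0,
        "odds_ratio": float(odds_ratio),
        "two_tailed_fisher_p": float(p_value),
    }
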