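"""Predicting gene mutability from transcriptional features.

The predictor is a conditional-inference classification tree: at each node
every covariate is tested for association with the class label (rank-based
two-sample / Kruskal-Wallis statistics for continuous covariates, exact
Fisher or chi-square for binary ones), p-values are Bonferroni-adjusted
across covariates, and the node becomes a leaf unless the best adjusted p
clears the significance criterion.  Splits of continuous covariates are
placed at the cutpoint maximizing the standardized two-sample statistic,
subject to a minimum bucket size.  Because growth is gated by multiplicity-
adjusted hypothesis tests rather than impurity improvement, the tree has
built-in type-I error control and needs no pruning.

Also here: the convergent-transcription (ConvT) flag (>100 bp of overlapping
sense and antisense transcription within a gene body) and the feature-table
filters applied before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CONTINUOUS_FEATURES",
    "BINARY_FEATURES",
    "FEATURE_COLUMNS",
    "CtreeParams",
    "CtreeNode",
    "CtreeModel",
    "convergent_transcription_flags",
    "prepare_features",
    "ctree_fit",
    "ctree_predict",
    "describe_tree",
    "tree_from_report",
    "evaluate_prediction",
]

CONTINUOUS_FEATURES = [
    "expression_tpm",
    "transcription_rate",
    "polII_density",
    "spt5_density",
]
BINARY_FEATURES = [
    "med12",
    "h3k4me1",
    "h3k36me3",
    "h3k79me2",
    "superenhancer",
    "convt",
]
FEATURE_COLUMNS = CONTINUOUS_FEATURES + BINARY_FEATURES


# ---------------------------------------------------------------------------
# ConvT rule and input filters
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int]


def _read_intervals(source: str | Path | Iterable) -> list[tuple]:
    if isinstance(source, (str, Path)):
        out = []
        with open(source) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                out.append(
                    (fields[0], int(fields[1]), int(fields[2]), *fields[3:4])
                )
        return out
    return [tuple(iv) for iv in source]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if start < end:
            out.append((start, end))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def convergent_transcription_flags(
    plus_intervals: str | Path | Iterable,
    minus_intervals: str | Path | Iterable,
    gene_bodies: str | Path | Iterable,
    min_overlap: int = 100,
) -> dict[str, int]:
    """ConvT flag per gene: 1 iff some contiguous stretch of overlapping
    sense and antisense transcription inside the gene body is strictly
    longer than ``min_overlap`` bp.

    Inputs are BED paths or (chrom, start, end[, name]) iterables; gene
    bodies must carry the gene name in the 4th column.  Plus- and
    minus-strand transcribed intervals are merged per chromosome before the
    overlap is computed, so abutting fragments count as one stretch.
    """
    plus_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in _read_intervals(plus_intervals):
        plus_by_chrom.setdefault(iv[0], []).append((iv[1], iv[2]))
    minus_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in _read_intervals(minus_intervals):
        minus_by_chrom.setdefault(iv[0], []).append((iv[1], iv[2]))
    convt_by_chrom = {
        chrom: _intersect(_merge(plus_by_chrom[chrom]), _merge(minus_by_chrom[chrom]))
        for chrom in set(plus_by_chrom) & set(minus_by_chrom)
    }
    flags: dict[str, int] = {}
    for iv in _read_intervals(gene_bodies):
        if len(iv) < 4:
            raise ValueError("gene body BED needs a name column")
        chrom, start, end, gene = iv[0], iv[1], iv[2], iv[3]
        hit = 0
        for c_start, c_end in convt_by_chrom.get(chrom, ()):
            if min(c_end, end) - max(c_start, start) > min_overlap:
                hit = 1
                break
        flags[gene] = max(flags.get(gene, 0), hit)
    return flags


def prepare_features(
    table: pd.DataFrame, background_freq_cutoff: float = 5e-4
) -> pd.DataFrame:
    """Filter and validate a gene feature table before fitting.

    Genes whose AID-null background mutation frequency exceeds the cutoff
    (strictly) are dropped as likely artifacts; the remaining rows are
    validated against the feature schema (continuous >= 0, binaries in
    {0, 1}).
    """
    for column in FEATURE_COLUMNS + ["background_freq"]:
        if column not in table.columns:
            raise ValueError(f"missing feature column: {column}")
    keep = table["background_freq"] <= background_freq_cutoff
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "prepare_features: dropped %d genes with background frequency > %g",
            dropped,
            background_freq_cutoff,
        )
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("no genes left after background-frequency filter")
    for column in CONTINUOUS_FEATURES:
        if (out[column] < 0).any():
            raise ValueError(f"negative values in continuous feature {column}")
    for column in BINARY_FEATURES:
        if not set(out[column].unique()) <= {0, 1}:
            raise ValueError(f"non-binary values in feature {column}")
    return out


# ---------------------------------------------------------------------------
# Conditional-inference tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtreeParams:
    """Stopping and split-selection parameters.

    ``alpha`` is the split criterion on Bonferroni-adjusted association
    p-values (0.05 corresponds to the conventional 0.95 criterion);
    ``minsplit`` is the minimum node size eligible for splitting and
    ``minbucket`` the minimum child size.
    """

    alpha: float = 0.05
    minsplit: int = 20
    minbucket: int = 7
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.minbucket > self.minsplit / 2:
            raise ValueError("minbucket must be <= minsplit / 2")


@dataclass
class CtreeNode:
    """One node: either a split (covariate set) or a leaf."""

    node_id: int
    n: int
    class_counts: dict[str, int]
    covariate: str | None = None
    p_adjusted: float | None = None
    cutpoint: float | None = None  # continuous: x <= cutpoint -> left
    level: int | None = None  # binary: x == level -> left
    left: "CtreeNode | None" = None
    right: "CtreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.covariate is None

    def proportions(self, classes: Sequence[str]) -> dict[str, float]:
        return {c: self.class_counts.get(c, 0) / self.n for c in classes}


@dataclass
class CtreeModel:
    root: CtreeNode
    classes: list[str]  # ordered by global frequency (desc), ties alphabetical
    covariates: list[str]
    binary_covariates: list[str]
    params: CtreeParams


def _association_p(
    x: np.ndarray, y_codes: np.ndarray, n_classes: int, binary: bool
) -> float:
    """Two-sided association p-value of one covariate with the label."""
    if np.all(x == x[0]):
        return 1.0
    if binary:
        table = np.zeros((2, n_classes), dtype=np.int64)
        for level in (0, 1):
            for c in range(n_classes):
                table[level, c] = int(np.sum((x == level) & (y_codes == c)))
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            return 1.0
        if n_classes == 2 and table.shape[1] == 2:
            return float(stats.fisher_exact(table, alternative="two-sided")[1])
        return float(stats.chi2_contingency(table, correction=False)[1])
    groups = [x[y_codes == c] for c in range(n_classes)]
    groups = [g for g in groups if g.size]
    if len(groups) < 2:
        return 1.0
    if len(groups) == 2:
        try:
            return float(
                stats.mannwhitneyu(
                    groups[0], groups[1], alternative="two-sided", method="asymptotic"
                ).pvalue
            )
        except ValueError:
            return 1.0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return 1.0


def _best_cutpoint(
    x: np.ndarray, y_codes: np.ndarray, n_classes: int, minbucket: int
) -> float | None:
    """Cutpoint maximizing the standardized split statistic.

    Candidates are midpoints between consecutive distinct values of ``x``;
    each is scored by the chi-square statistic of the 2 x K
    (left/right x class) table, computed cumulatively over the sort order.
    For two classes this is the square of the standardized two-sample
    statistic, so the argmax coincides.  Returns None when no candidate
    respects ``minbucket`` on both sides.
    """
    order = np.argsort(x, kind="mergesort")
    x_sorted = x[order]
    onehot = np.zeros((x.size, n_classes))
    onehot[np.arange(x.size), y_codes[order]] = 1.0
    cum = np.cumsum(onehot, axis=0)  # class counts left of each split point
    total = cum[-1]
    n = x.size
    sizes_left = np.arange(1, n + 1, dtype=float)

    boundary = x_sorted[:-1] < x_sorted[1:]  # split after position i allowed
    valid = (
        boundary
        & (sizes_left[:-1] >= minbucket)
        & ((n - sizes_left[:-1]) >= minbucket)
    )
    if not valid.any():
        return None
    left = cum[:-1][valid]
    n_left = sizes_left[:-1][valid]
    n_right = n - n_left
    expected_left = np.outer(n_left, total) / n
    expected_right = np.outer(n_right, total) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(
            (left - expected_left) ** 2 / expected_left
            + ((total - left) - expected_right) ** 2 / expected_right,
            axis=1,
        )
    best = int(np.argmax(chi2))
    idx = np.flatnonzero(valid)[best]
    return float((x_sorted[idx] + x_sorted[idx + 1]) / 2.0)


def ctree_fit(
    features: pd.DataFrame,
    labels: Sequence,
    params: CtreeParams = CtreeParams(),
    covariates: Sequence[str] | None = None,
) -> CtreeModel:
    """Fit a conditional-inference classification tree.

    ``features`` holds the covariate columns (non-covariate columns such as
    ``gene``/``label``/``background_freq`` are ignored when ``covariates``
    is not given); ``labels`` is the per-gene class.  Covariates whose
    observed values are a subset of {0, 1} are treated as binary.  The fit
    is deterministic for fixed inputs and parameters.
    """
    if covariates is None:
        covariates = [c for c in features.columns if c in FEATURE_COLUMNS] or [
            c
            for c in features.columns
            if c not in ("gene", "label", "background_freq")
            and np.issubdtype(features[c].dtype, np.number)
        ]
    covariates = list(covariates)
    X = features[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing covariate values are not supported")
    y = pd.Series(list(labels))
    if len(y) != len(X):
        raise ValueError("features and labels differ in length")
    class_counts = y.value_counts()
    classes = sorted(class_counts.index, key=lambda c: (-class_counts[c], str(c)))
    code_map = {c: i for i, c in enumerate(classes)}
    y_codes = y.map(code_map).to_numpy(dtype=int)
    binary = [
        c for c in covariates if set(np.unique(X[:, covariates.index(c)])) <= {0.0, 1.0}
    ]
    n_classes = len(classes)
    counter = iter(range(1, 10**9))

    def build(idx: np.ndarray, depth: int) -> CtreeNode:
        node = CtreeNode(
            node_id=next(counter),
            n=idx.size,
            class_counts={
                c: int(np.sum(y_codes[idx] == code_map[c])) for c in classes
            },
        )
        if idx.size < params.minsplit or len(np.unique(y_codes[idx])) < 2:
            return node
        if params.max_depth is not None and depth >= params.max_depth:
            return node
        p_values = np.array(
            [
                _association_p(
                    X[idx, j], y_codes[idx], n_classes, covariates[j] in binary
                )
                for j in range(len(covariates))
            ]
        )
        p_adj = np.minimum(p_values * len(covariates), 1.0)
        best_j = int(np.argmin(p_adj))
        if p_adj[best_j] > params.alpha:
            return node
        covariate = covariates[best_j]
        x = X[idx, best_j]
        if covariate in binary:
            left_mask = x == 0.0
            if left_mask.sum() < params.minbucket or (~left_mask).sum() < params.minbucket:
                return node
            node.level = 0
        else:
            cut = _best_cutpoint(x, y_codes[idx], n_classes, params.minbucket)
            if cut is None:
                return node
            node.cutpoint = cut
            left_mask = x <= cut
        node.covariate = covariate
        node.p_adjusted = float(p_adj[best_j])
        node.left = build(idx[left_mask], depth + 1)
        node.right = build(idx[~left_mask], depth + 1)
        return node

    root = build(np.arange(len(X)), 0)
    return CtreeModel(root, list(classes), covariates, binary, params)


def _route(model: CtreeModel, row: Mapping[str, float]) -> CtreeNode:
    node = model.root
    while not node.is_leaf:
        value = row[node.covariate]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing value for split covariate {node.covariate}")
        if node.cutpoint is not None:
            node = node.left if value <= node.cutpoint else node.right
        else:
            node = node.left if value == node.level else node.right
    return node


def ctree_predict(model: CtreeModel, features: pd.DataFrame) -> pd.DataFrame:
    """Route rows to leaves; return leaf proportions and the argmax class.

    Ties in leaf proportions break toward the globally more frequent class.
    Raises on missing values for split covariates (no surrogate splits).
    """
    needed = set()

    def collect(node: CtreeNode) -> None:
        if not node.is_leaf:
            needed.add(node.covariate)
            collect(node.left)
            collect(node.right)

    collect(model.root)
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"features lack split covariates: {sorted(missing)}")

    rows = []
    for _, row in features.iterrows():
        leaf = _route(model, row)
        props = leaf.proportions(model.classes)
        best = max(model.classes, key=lambda c: (props[c], -model.classes.index(c)))
        rows.append(
            {
                "leaf_id": leaf.node_id,
                "predicted_class": best,
                **{f"prop_{c}": props[c] for c in model.classes},
            }
        )
    out = pd.DataFrame(rows)
    if "gene" in features.columns:
        out.insert(0, "gene", features["gene"].to_numpy())
    return out


def describe_tree(model: CtreeModel) -> dict[str, Any]:
    """Serializable report of the fitted tree, ordered by node id."""
    nodes: list[dict[str, Any]] = []

    def walk(node: CtreeNode) -> None:
        entry: dict[str, Any] = {
            "node_id": node.node_id,
            "n": node.n,
            "class_counts": dict(node.class_counts),
        }
        if node.is_leaf:
            props = node.proportions(model.classes)
            entry["kind"] = "leaf"
            entry["class_proportions"] = props
            entry["predicted_class"] = max(
                model.classes, key=lambda c: (props[c], -model.classes.index(c))
            )
        else:
            entry.update(
                {
                    "kind": "split",
                    "covariate": node.covariate,
                    "p_adjusted": node.p_adjusted,
                    "cutpoint": node.cutpoint,
                    "level": node.level,
                    "left": node.left.node_id,
                    "right": node.right.node_id,
                }
            )
        nodes.append(entry)
        if not node.is_leaf:
            walk(node.left)
            walk(node.right)

    walk(model.root)
    nodes.sort(key=lambda e: e["node_id"])
    return {
        "classes": list(model.classes),
        "covariates": list(model.covariates),
        "binary_covariates": list(model.binary_covariates),
        "params": {
            "alpha": model.params.alpha,
            "minsplit": model.params.minsplit,
            "minbucket": model.params.minbucket,
            "max_depth": model.params.max_depth,
            "seed": model.params.seed,
        },
        "nodes": nodes,
    }


def tree_from_report(report: Mapping[str, Any]) -> CtreeModel:
    """Reconstruct a :class:`CtreeModel` from :func:`describe_tree` output."""
    entries = {e["node_id"]: e for e in report["nodes"]}

    def build(node_id: int) -> CtreeNode:
        e = entries[node_id]
        node = CtreeNode(
            node_id=e["node_id"],
            n=e["n"],
            class_counts={str(k): int(v) for k, v in e["class_counts"].items()},
        )
        if e["kind"] == "split":
            node.covariate = e["covariate"]
            node.p_adjusted = e["p_adjusted"]
            node.cutpoint = e["cutpoint"]
            node.level = e["level"]
            node.left = build(e["left"])
            node.right = build(e["right"])
        return node

    root_id = min(entries)
    params = CtreeParams(**report["params"])
    return CtreeModel(
        build(root_id),
        list(report["classes"]),
        list(report["covariates"]),
        list(report["binary_covariates"]),
        params,
    )


def evaluate_prediction(
    labels: Sequence,
    predictions: Sequence,
    leaf_ids: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Confusion matrix plus, when leaf assignments are given, per-leaf purity.

    Purity of a leaf is the fraction of its samples carrying the leaf's
    majority true label.
    """
    y_true = pd.Series(list(labels), name="true")
    y_pred = pd.Series(list(predictions), name="predicted")
    if len(y_true) != len(y_pred):
        raise ValueError("labels and predictions differ in length")
    confusion = pd.crosstab(y_true, y_pred)
    if leaf_ids is None:
        return confusion, None
    frame = pd.DataFrame({"leaf_id": list(leaf_ids), "true": y_true})
    rows = []
    for leaf_id, group in frame.groupby("leaf_id"):
        counts = group["true"].value_counts()
        majority = counts.index[0]
        rows.append(
            {
                "leaf_id": leaf_id,
                "n": len(group),
                "majority_class": majority,
                "purity": counts.iloc[0] / len(group),
            }
        )
    return confusion, pd.DataFrame(rows)
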