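"""Compositional similarity between change-attribute bins.

Mean Sørensen similarity is computed over all within-(study, land-use) site
pairs grouped by the bins of the two sites, expressed relative to the mean
similarity among unchanged pairs (UC-UC), and the bin rows are clustered by
complete linkage on (missing-cell renormalized) Manhattan distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .binning import MAGNITUDE_BINS, TIME_BINS, TREND_BINS, UC

_BIN_COLUMN = {"magnitude": "magnitude_bin", "trend": "trend_bin",
               "time": "time_bin"}
_BIN_ORDER = {"magnitude": [UC] + list(MAGNITUDE_BINS),
              "trend": [UC] + list(TREND_BINS),
              "time": [UC] + list(TIME_BINS)}


@dataclass
class SimilarityMatrix:
    """Symmetric bin x bin matrix of mean pairwise Sørensen similarity."""
    labels: list
    values: np.ndarray        # NaN where no pair qualifies
    n_pairs: np.ndarray
    n_studies: np.ndarray
    relative: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def cell(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def mean_similarity_by_bin(pairs: pd.DataFrame, attributes: pd.DataFrame,
                           attribute: str = "magnitude",
                           study_weighted: bool = False) -> SimilarityMatrix:
    """Mean Sørensen similarity for every (bin_a, bin_b) combination.

    Each qualifying pair contributes to the unordered cell of its two sites'
    bins; by default the cell is the unweighted mean over pairs
    (``study_weighted=True`` averages study means instead). Empty cells are
    missing with ``n_studies = 0``.
    """
    col = _BIN_COLUMN[attribute]
    bins = attributes.set_index("site_id")[col]
    labels = [b for b in _BIN_ORDER[attribute]]
    k = len(labels)
    idx = {b: i for i, b in enumerate(labels)}
    df = pairs.copy()
    df["bin_a"] = df["site_a"].map(bins)
    df["bin_b"] = df["site_b"].map(bins)
    df = df.dropna(subset=["bin_a", "bin_b", "sorensen"])

    values = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    n_studies = np.zeros((k, k), dtype=int)
    i_lo = np.minimum(df["bin_a"].map(idx), df["bin_b"].map(idx))
    i_hi = np.maximum(df["bin_a"].map(idx), df["bin_b"].map(idx))
    df = df.assign(_i=i_lo, _j=i_hi)
    for (i, j), cell in df.groupby(["_i", "_j"]):
        if study_weighted:
            m = float(cell.groupby("study_id")["sorensen"].mean().mean())
        else:
            m = float(cell["sorensen"].mean())
        values[i, j] = values[j, i] = m
        n_pairs[i, j] = n_pairs[j, i] = len(cell)
        ns = cell["study_id"].nunique()
        n_studies[i, j] = n_studies[j, i] = ns
    present = [i for i in range(k)
               if n_pairs[i, :].sum() + n_pairs[:, i].sum() > 0]
    sub = np.ix_(present, present)
    return SimilarityMatrix([labels[i] for i in present], values[sub],
                            n_pairs[sub], n_studies[sub])


def relative_to_uc(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Subtract the UC-UC mean similarity from every cell."""
    if UC not in matrix.labels:
        raise ValueError("UC-UC cell missing: no unchanged pairs")
    iu = matrix.labels.index(UC)
    base = matrix.values[iu, iu]
    if not np.isfinite(base):
        raise ValueError("UC-UC cell missing: no unchanged pairs")
    return SimilarityMatrix(list(matrix.labels), matrix.values - base,
                            matrix.n_pairs.copy(), matrix.n_studies.copy(),
                            relative=True)


def _row_distances(values: np.ndarray) -> np.ndarray:
    """Condensed Manhattan distances between rows, renormalized over the
    shared non-missing cells; rows with no shared cell get distance NaN."""
    k = values.shape[0]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            both = np.isfinite(values[i]) & np.isfinite(values[j])
            if not both.any():
                out.append(np.nan)
            else:
                d = np.abs(values[i, both] - values[j, both]).sum()
                out.append(d * values.shape[1] / both.sum())
    return np.asarray(out)


def cluster_bins(matrix: SimilarityMatrix) -> dict:
    """Complete-linkage clustering of bin rows on Manhattan distances.

    Returns a nested merge tree ``{"label"| "children", "height"}`` with a
    deterministic left-child ordering by label. Requires >= 2 populated rows.
    """
    keep = [i for i in range(len(matrix.labels))
            if np.isfinite(matrix.values[i]).any()]
    if len(keep) < 2:
        raise ValueError("clustering needs at least 2 populated rows")
    labels = [matrix.labels[i] for i in keep]
    vals = matrix.values[np.ix_(keep, keep)]
    dist = _row_distances(vals)
    if np.isnan(dist).any():
        finite = dist[np.isfinite(dist)]
        fill = (finite.max() * 2 + 1) if finite.size else 1.0
        dist = np.where(np.isnan(dist), fill, dist)
    Z = linkage(dist, method="complete")

    nodes = [{"label": lab, "height": 0.0, "_order": lab} for lab in labels]
    for a, b, h, _ in Z:
        ca, cb = nodes[int(a)], nodes[int(b)]
        left, right = sorted([ca, cb], key=lambda n: n["_order"])
        nodes.append({"children": [left, right], "height": float(h),
                      "_order": left["_order"]})
    root = nodes[-1]

    def _strip(node):
        node = dict(node)
        node.pop("_order", None)
        if "children" in node:
            node["children"] = [_strip(c) for c in node["children"]]
        return node

    return _strip(root)


def merge_heights(tree: dict) -> list:
    """Sorted positive merge heights of a cluster tree (for testing/summary)."""
    out = []

    def _walk(node):
        if "children" in node:
            out.append(node["height"])
            for c in node["children"]:
                _walk(c)

    _walk(tree)
    return sorted(out)


def tree_leaves(tree: dict) -> list:
    """Leaf labels of a cluster tree in left-to-right order."""
    if "label" in tree:
        return [tree["label"]]
    return [leaf for c in tree["children"] for leaf in tree_leaves(c)]
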