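"""Cross-species comparison layer: map correlations, corridor overlap,
and proxy-species ranking.

Continuous products (suitability, circuit current, normalized corridor
surfaces) are compared by pairwise Pearson correlation over jointly
valid cells; binary corridor masks are compared by percent overlap
(symmetric Jaccard percentage by default). The proxy ranking orders
models by how well each predicts the single-species models on average,
mirroring the question of which single species best stands in for the
assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "ComparisonMatrix",
    "map_correlation",
    "percent_overlap",
    "comparison_matrix",
    "proxy_ranking",
]

STACKED_LABEL = "stacked"


@dataclass
class ComparisonMatrix:
    """Square labelled matrix of a pairwise comparison statistic."""

    labels: list[str]
    values: pd.DataFrame
    statistic: str  # "pearson_r" | "percent_overlap"
    product: str = ""
    scaling: str = ""

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# statistic: {self.statistic}\n")
            if self.product:
                fh.write(f"# product: {self.product}\n")
            if self.scaling:
                fh.write(f"# scaling: {self.scaling}\n")
            self.values.to_csv(fh)


def map_correlation(a: RasterGrid, b: RasterGrid) -> float:
    """Pearson r between two maps over jointly valid, finite cells."""
    a.require_compatible(b, "map")
    joint = a.valid_mask & b.valid_mask & np.isfinite(a.values) & np.isfinite(b.values)
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly valid cells")
    va, vb = a.values[joint], b.values[joint]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined: one map is constant on joint cells")
    return float(np.corrcoef(va, vb)[0, 1])


def percent_overlap(a: np.ndarray, b: np.ndarray,
                    convention: str = "jaccard") -> float:
    """Percent overlap of two corridor masks.

    ``'jaccard'`` (default): 100 * |A n B| / |A u B| (symmetric).
    ``'mean_asymmetric'``: the mean of 100*|A n B|/|A| and 100*|A n B|/|B|.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("corridor masks must share a grid")
    if not a.any() or not b.any():
        raise ValueError("corridor masks must be nonempty")
    inter = float(np.sum(a & b))
    if convention == "jaccard":
        return 100.0 * inter / float(np.sum(a | b))
    if convention == "mean_asymmetric":
        return 50.0 * (inter / a.sum() + inter / b.sum())
    raise ValueError(f"unknown overlap convention '{convention}'")


def comparison_matrix(
    products: dict[str, RasterGrid | np.ndarray],
    statistic: str = "pearson_r",
    product: str = "",
    scaling: str = "",
    overlap_convention: str = "jaccard",
) -> ComparisonMatrix:
    """Full pairwise comparison matrix over labelled products.

    ``statistic='pearson_r'`` expects RasterGrids, ``'percent_overlap'``
    expects boolean masks. The diagonal is 1 (r) or 100 (overlap).
    """
    labels = list(products)
    if len(labels) < 2:
        raise ValueError("need at least two labelled products")
    n = len(labels)
    mat = np.empty((n, n))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if j < i:
                mat[i, j] = mat[j, i]
            elif i == j:
                mat[i, j] = 1.0 if statistic == "pearson_r" else 100.0
            elif statistic == "pearson_r":
                mat[i, j] = map_correlation(products[la], products[lb])
            elif statistic == "percent_overlap":
                mat[i, j] = percent_overlap(
                    products[la], products[lb], convention=overlap_convention
                )
            else:
                raise ValueError(f"unknown statistic '{statistic}'")
    return ComparisonMatrix(
        labels=labels,
        values=pd.DataFrame(mat, index=labels, columns=labels),
        statistic=statistic,
        product=product,
        scaling=scaling,
    )


def proxy_ranking(m: ComparisonMatrix) -> pd.DataFrame:
    """Rank models by mean pairwise value against single-species models.

    Each label (including the stacked model) is scored by the mean of
    its off-diagonal entries against the single-species labels only
    (self and the stacked model are excluded from the averaging
    targets). Labels are sorted descending; exact ties are broken
    alphabetically and flagged.
    """
    labels = m.labels
    if len(labels) < 3:
        raise ValueError("proxy ranking needs at least three labels")
    singles = [l for l in labels if l != STACKED_LABEL]
    scores = {}
    for label in labels:
        targets = [s for s in singles if s != label]
        scores[label] = float(np.mean([m.values.loc[label, t] for t in targets]))
    out = pd.DataFrame(
        {"label": list(scores), "mean_pairwise": list(scores.values())}
    )
    out = out.sort_values(
        ["mean_pairwise", "label"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["tied"] = out["mean_pairwise"].duplicated(keep=False)
    return out
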