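"""Position-by-position rank-sum comparison of gene groups, and group set algebra.

The observation unit is the per-gene window mean: at each window center the
two groups contribute one value per gene with probes in the window, and a
two-sided unpaired Wilcoxon rank-sum test is applied (exact when both
groups have <= 8 observations and there are no ties, otherwise the normal
approximation with tie and continuity corrections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .profile import _window_grid, _window_stats

__all__ = [
    "WilcoxonTrack",
    "per_gene_window_matrix",
    "rank_sum_p",
    "wilcoxon_track",
    "group_ops",
]

EXACT_MAX_N = 8  # exact null enumeration up to this group size (tie-free)


@dataclass
class WilcoxonTrack:
    """Per-window two-sided rank-sum p-values and the significance mask."""

    window_centers: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    n_group_a: np.ndarray
    n_group_b: np.ndarray
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.window_centers,
                "p": self.p_value,
                "significant": self.significant,
                "n_a": self.n_group_a,
                "n_b": self.n_group_b,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")


def per_gene_window_matrix(
    signals: pd.DataFrame,
    genes: set[str],
    width: float = 30.0,
    step: float = 10.0,
    flank: float = 600.0,
) -> pd.DataFrame:
    """Genes x window-centers matrix of per-gene mean log2 ratios.

    Entry (g, c) is the mean log2 ratio of gene g's probes with relative
    position in [c - width/2, c + width/2); NaN where the gene has no probe
    in the window.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    centers = _window_grid(flank, step)
    sub = signals[signals["gene_id"].isin(genes)]
    rows = {}
    for gene, g in sub.groupby("gene_id", sort=True):
        sums, counts = _window_stats(
            g["rel_pos"].to_numpy(float), g["log2_ratio"].to_numpy(float), centers, width
        )
        with np.errstate(invalid="ignore"):
            rows[gene] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    for gene in genes - set(rows):
        rows[gene] = np.full(len(centers), np.nan)
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=centers)
    return mat.sort_index()


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Uses exact enumeration of the rank-sum null when both samples have at
    most `EXACT_MAX_N` observations and no ties are present; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def wilcoxon_track(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> WilcoxonTrack:
    """Windowwise two-sided rank-sum comparison of two gene-group matrices.

    Windows where either group has fewer than two non-missing genes get a
    missing p-value and are never significant. By default raw p-values are
    thresholded at ``alpha`` (no multiple-testing correction);
    ``bh_correct`` switches to Benjamini-Hochberg adjusted p-values.
    """
    if not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("group matrices must share the same window grid")
    centers = matrix_a.columns.to_numpy(float)
    p = np.full(len(centers), np.nan)
    n_a = np.zeros(len(centers), dtype=int)
    n_b = np.zeros(len(centers), dtype=int)
    va = matrix_a.to_numpy(float)
    vb = matrix_b.to_numpy(float)
    for j in range(len(centers)):
        a = va[:, j]
        b = vb[:, j]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        n_a[j], n_b[j] = len(a), len(b)
        if len(a) >= 2 and len(b) >= 2:
            p[j] = rank_sum_p(a, b)
    if bh_correct:
        ok = ~np.isnan(p)
        if ok.any():
            p = p.copy()
            p[ok] = multipletests(p[ok], method="fdr_bh")[1]
    significant = np.where(np.isnan(p), False, p < alpha)
    return WilcoxonTrack(centers, p, significant.astype(bool), n_a, n_b, alpha)


def group_ops(groups: dict[str, set[str]], a: str, b: str) -> dict:
    """Set algebra between two named gene groups, with counts.

    Returns the intersection, both directed differences and the union,
    each with its size. Unknown group names raise a KeyError listing the
    available groups.
    """
    for name in (a, b):
        if name not in groups:
            raise KeyError(
                f"unknown group {name!r}; available: {sorted(groups)}"
            )
    ga, gb = groups[a], groups[b]
    out = {
        "a": a,
        "b": b,
        "size_a": len(ga),
        "size_b": len(gb),
        "intersection": sorted(ga & gb),
        "a_minus_b": sorted(ga - gb),
        "b_minus_a": sorted(gb - ga),
        "union": sorted(ga | gb),
    }
    out["n_intersection"] = len(out["intersection"])
    out["n_a_minus_b"] = len(out["a_minus_b"])
    out["n_b_minus_a"] = len(out["b_minus_a"])
    out["n_union"] = len(out["union"])
    return out
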