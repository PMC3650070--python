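"""From two-channel probe intensities to TSS-anchored aggregate profiles.

The chain is: per-probe log2(MNase/gDNA) ratios, replicate averaging,
strand-aware mapping of probe centers onto a TSS-relative axis, sliding
30/10 bp window aggregation over a gene set, and lowess smoothing of the
windowed track.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

__all__ = [
    "WindowTrack",
    "SmoothTrack",
    "compute_log2_ratio",
    "median_center",
    "average_replicates",
    "replicate_concordance",
    "map_probes_to_tss",
    "aggregate_windows",
    "smooth_lowess",
]


@dataclass
class WindowTrack:
    """Aggregate nucleosome-density profile on a fixed window grid.

    ``mean_signal`` is NaN exactly where ``n_points`` is zero (windows with
    no probe in any selected gene, e.g. repeat-masked gaps).
    """

    window_centers: np.ndarray
    mean_signal: np.ndarray
    n_points: np.ndarray
    window_width: float = 30.0
    step: float = 10.0

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        self.n_points = np.asarray(self.n_points, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.window_centers,
                "value": self.mean_signal,
                "n_points": self.n_points,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")

    @classmethod
    def from_tsv(cls, path, window_width: float = 30.0, step: float = 10.0) -> "WindowTrack":
        df = pd.read_csv(path, sep="\t", na_values=".")
        return cls(
            df["position"].to_numpy(float),
            df["value"].to_numpy(float),
            df["n_points"].to_numpy(),
            window_width,
            step,
        )


@dataclass
class SmoothTrack:
    """Lowess-smoothed profile evaluated at the non-missing window centers."""

    positions: np.ndarray
    values: np.ndarray
    span_f: float = 0.05

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")

    @classmethod
    def from_tsv(cls, path, span_f: float = 0.05) -> "SmoothTrack":
        df = pd.read_csv(path, sep="\t", na_values=".")
        return cls(df["position"].to_numpy(float), df["value"].to_numpy(float), span_f)


def compute_log2_ratio(signals: pd.DataFrame) -> pd.DataFrame:
    """Add a ``log2_ratio`` = log2(mnase/gdna) column to a signal table.

    Channel normalization is assumed to have happened upstream; both
    intensities must be strictly positive.
    """
    bad = signals[(signals["mnase"] <= 0) | (signals["gdna"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive intensity for probe_id {bad['probe_id'].iloc[0]!r}"
        )
    out = signals.copy()
    out["log2_ratio"] = np.log2(out["mnase"].to_numpy() / out["gdna"].to_numpy())
    return out


def median_center(ratios: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-sample median log2 ratio (optional, off by default)."""
    out = ratios.copy()
    med = out.groupby("sample_id")["log2_ratio"].transform("median")
    out["log2_ratio"] = out["log2_ratio"] - med
    return out


def average_replicates(ratios: pd.DataFrame) -> pd.DataFrame:
    """Average the log2 ratio across replicates, per probe and sample.

    Probes present in only a subset of the replicates are averaged over the
    available values, with a logged warning.
    """
    n_reps = ratios.groupby("sample_id")["replicate_id"].nunique()
    grouped = ratios.groupby(["sample_id", "probe_id"], sort=False)["log2_ratio"]
    out = grouped.mean().reset_index()
    counts = grouped.size().reset_index(name="n")
    merged = counts.merge(n_reps.rename("n_reps"), on="sample_id")
    partial = merged[merged["n"] < merged["n_reps"]]
    if len(partial):
        logger.warning(
            "%d probes are missing from at least one replicate; "
            "averaged over the available replicates", len(partial)
        )
    return out


def replicate_concordance(rep1: pd.Series, rep2: pd.Series) -> float:
    """Squared Pearson correlation of two replicates over their common probes.

    Both series are indexed by probe id. Returns NaN when fewer than three
    probes are shared or either replicate has zero variance.
    """
    common = rep1.index.intersection(rep2.index)
    if len(common) < 3:
        raise ValueError(f"replicates share only {len(common)} probes (need >= 3)")
    a = rep1.loc[common].to_numpy(float)
    b = rep2.loc[common].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def map_probes_to_tss(
    probes: pd.DataFrame,
    signal: pd.Series,
    tss: pd.DataFrame,
    flank: float = 600.0,
) -> pd.DataFrame:
    """Place per-probe signal on strand-adjusted TSS-relative coordinates.

    For each gene, every probe on the gene's chromosome whose strand-adjusted
    offset (``center - tss`` on '+', ``tss - center`` on '-') lies within
    ``[-flank, +flank]`` contributes one record; a probe near two close genes
    contributes to both.

    Parameters
    ----------
    probes
        Probe definitions from :func:`nucleoprof.io.read_probes`.
    signal
        Per-probe values (e.g. replicate-averaged log2 ratios) indexed by
        probe id.
    tss
        TSS annotation (gene_id, chrom, tss, strand).

    Returns
    -------
    DataFrame with columns ``gene_id, probe_id, rel_pos, log2_ratio``.
    """
    pr = probes.merge(signal.rename("log2_ratio"), left_on="probe_id", right_index=True)
    pieces = []
    for gene in tss.itertuples(index=False):
        sub = pr[pr["chrom"] == gene.chrom]
        if gene.strand == "+":
            rel = sub["center"].to_numpy(float) - gene.tss
        else:
            rel = gene.tss - sub["center"].to_numpy(float)
        keep = np.abs(rel) <= flank
        if not keep.any():
            logger.warning("gene %s has no probes within +-%g bp of its TSS", gene.gene_id, flank)
            continue
        piece = pd.DataFrame(
            {
                "gene_id": gene.gene_id,
                "probe_id": sub["probe_id"].to_numpy()[keep],
                "rel_pos": rel[keep],
                "log2_ratio": sub["log2_ratio"].to_numpy(float)[keep],
            }
        )
        pieces.append(piece)
    if not pieces:
        return pd.DataFrame(columns=["gene_id", "probe_id", "rel_pos", "log2_ratio"])
    return pd.concat(pieces, ignore_index=True)


def _window_grid(flank: float, step: float) -> np.ndarray:
    n = int(round(2 * flank / step))
    return -flank + step * np.arange(n + 1)


def _window_stats(rel_pos: np.ndarray, values: np.ndarray, centers: np.ndarray,
                  width: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sums and counts with half-open membership [c-w/2, c+w/2)."""
    order = np.argsort(rel_pos, kind="stable")
    pos = rel_pos[order]
    val = values[order]
    csum = np.concatenate([[0.0], np.cumsum(val)])
    lo = np.searchsorted(pos, centers - width / 2, side="left")
    hi = np.searchsorted(pos, centers + width / 2, side="left")
    return csum[hi] - csum[lo], (hi - lo)


def aggregate_windows(
    signals: pd.DataFrame,
    genes: set[str] | None = None,
    width: float = 30.0,
    step: float = 10.0,
    flank: float = 600.0,
    per_gene_mean: bool = False,
) -> WindowTrack:
    """Tally TSS-relative records into a sliding-window aggregate track.

    Window centers run from ``-flank`` to ``+flank`` in steps of ``step``;
    a record at relative position x belongs to window c iff
    ``c - width/2 <= x < c + width/2``. By default all (gene, probe) records
    are pooled with equal weight; with ``per_gene_mean`` the track is the
    unweighted mean of per-gene window means (``n_points`` then counts
    contributing genes).
    """
    if genes is not None:
        if len(genes) == 0:
            raise ValueError("empty gene set")
        signals = signals[signals["gene_id"].isin(genes)]
    if width < step:
        raise ValueError("window width must be >= step")
    centers = _window_grid(flank, step)
    rel = signals["rel_pos"].to_numpy(float)
    val = signals["log2_ratio"].to_numpy(float)
    if not per_gene_mean:
        sums, counts = _window_stats(rel, val, centers, width)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        gene_ids = signals["gene_id"].to_numpy()
        acc = np.zeros_like(centers)
        counts = np.zeros(len(centers), dtype=int)
        for gene in pd.unique(gene_ids):
            m = gene_ids == gene
            s, c = _window_stats(rel[m], val[m], centers, width)
            has = c > 0
            acc[has] += s[has] / c[has]
            counts += has
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    return WindowTrack(centers, mean, counts, width, step)


def smooth_lowess(
    track: WindowTrack, span_f: float = 0.05, iterations: int = 3
) -> SmoothTrack:
    """Lowess-smooth a window track (tricube weights, robustifying passes).

    ``span_f`` is the fraction of points in each local fit. Missing windows
    are excluded, not imputed; the smoother is evaluated at the remaining
    window centers.
    """
    ok = ~np.isnan(track.mean_signal)
    n = int(ok.sum())
    need = max(3, math.ceil(span_f * max(n, 1)), 2)
    if n < need:
        raise ValueError(
            f"only {n} non-missing windows; need >= {need} — consider a larger span_f"
        )
    x = track.window_centers[ok]
    y = track.mean_signal[ok]
    fitted = _sm_lowess(y, x, frac=span_f, it=iterations, return_sorted=False)
    return SmoothTrack(x, fitted, span_f)
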