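"""Model/Results facade over the profiling pipeline.

`NucleosomeProfile` plays the role of a model object built from data
tables; `fit()` runs windowing, lowess smoothing, peak calling and NDR
sizing and returns a `NucleosomeProfileResult` carrying the tracks, the
labeled peaks, spacings, the NDR call and occupancy ratio, with a
`summary()` table and a `plot()`. `GroupComparison` does the same for the
windowwise rank-sum comparison of two gene groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compare as _compare
from . import peaks as _peaks
from . import profile as _profile

__all__ = [
    "NucleosomeProfile",
    "NucleosomeProfileResult",
    "GroupComparison",
    "GroupComparisonResult",
]


class NucleosomeProfile:
    """TSS-anchored aggregate nucleosome-density profile model.

    Parameters
    ----------
    rel_signals
        TSS-relative probe records (gene_id, rel_pos, log2_ratio), e.g.
        from :func:`nucleoprof.profile.map_probes_to_tss`.
    genes
        Optional gene subset to aggregate over (default: all genes present).
    window, step, flank
        Sliding-window geometry in bp.
    span_f
        Lowess span as a fraction of the non-missing windows.
    per_gene_mean
        Aggregate as the unweighted mean of per-gene window means instead
        of pooling all probe records.
    """

    def __init__(
        self,
        rel_signals: pd.DataFrame,
        genes: set[str] | None = None,
        window: float = 30.0,
        step: float = 10.0,
        flank: float = 600.0,
        span_f: float = 0.05,
        per_gene_mean: bool = False,
    ) -> None:
        self.rel_signals = rel_signals
        self.genes = set(genes) if genes is not None else None
        self.window = window
        self.step = step
        self.flank = flank
        self.span_f = span_f
        self.per_gene_mean = per_gene_mean

    @classmethod
    def from_tables(
        cls,
        probes: pd.DataFrame,
        signals: pd.DataFrame,
        tss: pd.DataFrame,
        sample_id: str | None = None,
        median_center: bool = False,
        **kwargs,
    ) -> "NucleosomeProfile":
        """Build the model from probe, two-channel signal and TSS tables.

        Computes log2(MNase/gDNA) per probe and replicate, averages
        replicates within ``sample_id`` (default: the only sample present)
        and maps probe centers onto the TSS-relative axis.
        """
        ratios = _profile.compute_log2_ratio(signals)
        if sample_id is not None:
            ratios = ratios[ratios["sample_id"] == sample_id]
            if not len(ratios):
                raise ValueError(f"no rows for sample_id {sample_id!r}")
        if median_center:
            ratios = _profile.median_center(ratios)
        averaged = _profile.average_replicates(ratios)
        per_probe = averaged.set_index("probe_id")["log2_ratio"]
        flank = kwargs.get("flank", 600.0)
        rel = _profile.map_probes_to_tss(probes, per_probe, tss, flank=flank)
        return cls(rel, **kwargs)

    def fit(
        self,
        min_prominence: float = 0.05,
        min_separation: float = 100.0,
        fragment_model: _peaks.FragmentSizeModel | None = None,
    ) -> "NucleosomeProfileResult":
        """Window, smooth, call peaks and size the NDR."""
        track = _profile.aggregate_windows(
            self.rel_signals,
            self.genes,
            width=self.window,
            step=self.step,
            flank=self.flank,
            per_gene_mean=self.per_gene_mean,
        )
        smooth = _profile.smooth_lowess(track, span_f=self.span_f)
        peakset = _peaks.call_peaks(smooth, min_prominence, min_separation)
        model = fragment_model or _peaks.FragmentSizeModel()
        ndr = _peaks.ndr_width(peakset, model)
        return NucleosomeProfileResult(self, track, smooth, peakset, ndr, model)


@dataclass
class NucleosomeProfileResult:
    """Fitted aggregate profile: tracks, labeled peaks, NDR, ratios."""

    model: NucleosomeProfile
    window_track: _profile.WindowTrack
    smooth_track: _profile.SmoothTrack
    peaks: _peaks.PeakSet
    ndr: _peaks.NdrCall
    fragment_model: _peaks.FragmentSizeModel

    def spacings(self) -> np.ndarray:
        return _peaks.peak_spacings(self.peaks)

    def occupancy_ratio(self, scale: str = "density") -> float:
        return _peaks.occupancy_ratio(self.peaks, scale=scale)

    def summary(self) -> str:
        lines = ["Nucleosome profile fit", "=" * 52]
        m = self.model
        n_genes = m.rel_signals["gene_id"].nunique() if m.genes is None else len(m.genes)
        lines.append(
            f"genes: {n_genes}   window/step/flank: "
            f"{m.window:g}/{m.step:g}/{m.flank:g} bp   lowess f: {m.span_f:g}"
        )
        lines.append("-" * 52)
        lines.append(f"{'label':>6} {'center (bp)':>12} {'amplitude':>11} {'prominence':>11}")
        for p in self.peaks:
            lines.append(
                f"{p.label:>+6d} {p.center:>12.1f} {p.amplitude:>11.3f} {p.prominence:>11.3f}"
            )
        if not len(self.peaks):
            lines.append("  (no peaks called)")
        sp = self.spacings()
        if len(sp):
            lines.append("spacings (bp): " + ", ".join(f"{s:.0f}" for s in sp))
        if self.ndr.called:
            lines.append(
                f"NDR: -1/+1 separation {self.ndr.separation:.0f} bp - footprint "
                f"{self.ndr.footprint:.0f} bp = width {self.ndr.width:.0f} bp"
            )
            try:
                lines.append(f"-1/+1 occupancy ratio (density scale): "
                             f"{self.occupancy_ratio():.3f}")
            except ValueError:
                pass
        else:
            lines.append(f"NDR: not called ({self.ndr.reason})")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Windowed points, the lowess trend line and the labeled peaks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.2))
        t = self.window_track
        ax.plot(t.window_centers, t.mean_signal, ".", ms=3, color="0.6",
                label="30/10 bp windows")
        s = self.smooth_track
        ax.plot(s.positions, s.values, "-", color="tab:blue",
                label=f"lowess f={s.span_f:g}")
        for p in self.peaks:
            ax.annotate(f"{p.label:+d}", (p.center, p.amplitude),
                        textcoords="offset points", xytext=(0, 6), ha="center")
        if self.ndr.called:
            up, down = self.peaks.get(-1), self.peaks.get(1)
            ax.axvspan(up.center, down.center, color="tab:orange", alpha=0.15,
                       label=f"NDR {self.ndr.width:.0f} bp")
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("position relative to TSS (bp)")
        ax.set_ylabel("log2(MNase/gDNA)")
        ax.legend(fontsize=8)
        return ax


class GroupComparison:
    """Windowwise rank-sum comparison between two gene groups."""

    def __init__(
        self,
        rel_signals: pd.DataFrame,
        genes_a: set[str],
        genes_b: set[str],
        window: float = 30.0,
        step: float = 10.0,
        flank: float = 600.0,
    ) -> None:
        if not genes_a or not genes_b:
            raise ValueError("both gene groups must be nonempty")
        self.rel_signals = rel_signals
        self.genes_a = set(genes_a)
        self.genes_b = set(genes_b)
        self.window = window
        self.step = step
        self.flank = flank

    def fit(self, alpha: float = 0.05, bh_correct: bool = False) -> "GroupComparisonResult":
        mat_a = _compare.per_gene_window_matrix(
            self.rel_signals, self.genes_a, self.window, self.step, self.flank
        )
        mat_b = _compare.per_gene_window_matrix(
            self.rel_signals, self.genes_b, self.window, self.step, self.flank
        )
        track = _compare.wilcoxon_track(mat_a, mat_b, alpha=alpha, bh_correct=bh_correct)
        return GroupComparisonResult(self, mat_a, mat_b, track)


@dataclass
class GroupComparisonResult:
    model: GroupComparison
    matrix_a: pd.DataFrame
    matrix_b: pd.DataFrame
    track: _compare.WilcoxonTrack

    def significant_windows(self) -> np.ndarray:
        return self.track.window_centers[self.track.significant]

    def summary(self) -> str:
        t = self.track
        tested = int((~np.isnan(t.p_value)).sum())
        nsig = int(t.significant.sum())
        lines = [
            "Group comparison (two-sided Wilcoxon rank sum)",
            "=" * 52,
            f"group A: {len(self.model.genes_a)} genes   "
            f"group B: {len(self.model.genes_b)} genes   alpha: {t.alpha:g}",
            f"windows tested: {tested} of {len(t.window_centers)}   "
            f"significant: {nsig}",
        ]
        sig = self.significant_windows()
        if len(sig):
            lines.append(
                "significant window centers (bp): "
                + ", ".join(f"{c:.0f}" for c in sig)
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.2))
        t = self.track
        ax.plot(t.window_centers, -np.log10(t.p_value), "-", color="0.4")
        ax.axhline(-np.log10(t.alpha), color="tab:red", lw=0.8, ls="--",
                   label=f"p = {t.alpha:g}")
        for c in self.significant_windows():
            ax.axvline(c, color="tab:green", alpha=0.25, lw=2)
        ax.set_xlabel("position relative to TSS (bp)")
        ax.set_ylabel("-log10 p")
        ax.legend(fontsize=8)
        return ax
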