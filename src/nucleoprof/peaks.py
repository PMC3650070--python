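"""Nucleosome peak calling, labeling, NDR sizing and occupancy ratios.

Peaks are local maxima of the smoothed aggregate profile, retained greedily
in order of decreasing prominence subject to a minimum separation, then
labeled -n..-1, +1..+n outward from the TSS. The nucleosome-depleted
region (NDR) between the -1 and +1 peaks is sized as their center-to-center
separation minus one nucleosome footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .profile import SmoothTrack

__all__ = [
    "FragmentSizeModel",
    "fragment_size_model",
    "NucleosomePeak",
    "PeakSet",
    "NdrCall",
    "call_peaks",
    "label_peaks",
    "peak_spacings",
    "ndr_width",
    "ndr_from_separation",
    "occupancy_ratio",
    "percent_reduction",
]


@dataclass(frozen=True)
class FragmentSizeModel:
    """Fragment-size arithmetic from the mono-/di-nucleosome gel bands.

    With a reference mono-nucleosome size ``mono_ref``, the linker length
    range is ``di_range - 2*mono_ref`` and the expected peak-to-peak
    nucleosome spacing is ``mono_ref + linker``. ``footprint`` is the
    nucleosome length subtracted from the -1/+1 separation to size the NDR.
    """

    mono_range: tuple[float, float] = (150.0, 175.0)
    di_range: tuple[float, float] = (320.0, 360.0)
    mono_ref: float = 150.0
    footprint: float = 160.0
    linker_range: tuple[float, float] = field(init=False)
    spacing_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("mono_range", self.mono_range), ("di_range", self.di_range)):
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        di_lo, di_hi = self.di_range
        if di_lo < 2 * self.mono_ref:
            raise ValueError(
                f"di-nucleosome band low edge {di_lo} < 2*mono_ref {2 * self.mono_ref}: "
                "negative linker"
            )
        object.__setattr__(
            self, "linker_range", (di_lo - 2 * self.mono_ref, di_hi - 2 * self.mono_ref)
        )
        object.__setattr__(
            self,
            "spacing_range",
            (self.mono_ref + self.linker_range[0], self.mono_ref + self.linker_range[1]),
        )


def fragment_size_model(
    mono_range=(150.0, 175.0),
    di_range=(320.0, 360.0),
    mono_ref: float = 150.0,
    footprint: float = 160.0,
) -> FragmentSizeModel:
    """Derive linker and spacing ranges from gel-band fragment sizes."""
    return FragmentSizeModel(tuple(mono_range), tuple(di_range), mono_ref, footprint)


@dataclass
class NucleosomePeak:
    label: int
    center: float
    amplitude: float
    prominence: float


@dataclass
class PeakSet:
    """Labeled nucleosome peaks ordered by center, with caller parameters."""

    peaks: list[NucleosomePeak]
    min_prominence: float = 0.05
    min_separation: float = 100.0

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks], dtype=float)

    def get(self, label: int) -> NucleosomePeak | None:
        for p in self.peaks:
            if p.label == label:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.peaks],
                "center": [p.center for p in self.peaks],
                "amplitude": [p.amplitude for p in self.peaks],
                "prominence": [p.prominence for p in self.peaks],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")


@dataclass
class NdrCall:
    """NDR between the -1 and +1 peaks: width = separation - footprint."""

    separation: float | None
    width: float | None
    footprint: float
    reason: str | None = None

    @property
    def called(self) -> bool:
        return self.width is not None


def _plateau_maxima(positions: np.ndarray, values: np.ndarray):
    """Interior local maxima; plateaus are reported at their centroid."""
    idx, props = find_peaks(values, plateau_size=(1, None))
    centers, amps, repr_idx = [], [], []
    for k, i in enumerate(idx):
        left, right = props["left_edges"][k], props["right_edges"][k]
        centers.append(float(positions[left : right + 1].mean()))
        amps.append(float(values[i]))
        repr_idx.append(int(i))
    return np.array(centers), np.array(amps), np.array(repr_idx, dtype=int)


def call_peaks(
    track: SmoothTrack,
    min_prominence: float = 0.05,
    min_separation: float = 100.0,
) -> PeakSet:
    """Call labeled nucleosome peaks on a smoothed profile.

    Candidate peaks are interior local maxima (plateaus collapse to their
    centroid) with topographic prominence >= ``min_prominence``; they are
    retained greedily in decreasing prominence order, discarding any
    candidate within ``min_separation`` bp of an already retained peak.
    An empty result is not an error.
    """
    if len(track.positions) < 3:
        raise ValueError("need at least 3 track points to call peaks")
    pos = np.asarray(track.positions, float)
    val = np.asarray(track.values, float)
    centers, amps, idx = _plateau_maxima(pos, val)
    if len(idx) == 0:
        return PeakSet([], min_prominence, min_separation)
    prom = peak_prominences(val, idx)[0]
    keep_mask = prom >= min_prominence
    centers, amps, prom = centers[keep_mask], amps[keep_mask], prom[keep_mask]
    order = np.argsort(-prom, kind="stable")
    kept: list[int] = []
    for i in order:
        if all(abs(centers[i] - centers[j]) >= min_separation for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: centers[i])
    peaks = [
        NucleosomePeak(0, float(centers[i]), float(amps[i]), float(prom[i])) for i in kept
    ]
    return label_peaks(PeakSet(peaks, min_prominence, min_separation))


def label_peaks(peakset: PeakSet) -> PeakSet:
    """Assign -n..-1 / +1..+n labels outward from the TSS.

    Peaks at center >= 0 are labeled +1, +2, ... in increasing center order;
    peaks at center < 0 are labeled -1, -2, ... moving upstream. A peak at
    exactly 0 is +1.
    """
    peaks = sorted(peakset.peaks, key=lambda p: p.center)
    neg = [p for p in peaks if p.center < 0]
    pos = [p for p in peaks if p.center >= 0]
    for i, p in enumerate(reversed(neg), start=1):
        p.label = -i
    for i, p in enumerate(pos, start=1):
        p.label = i
    peakset.peaks = peaks
    return peakset


def peak_spacings(peakset: PeakSet) -> np.ndarray:
    """Successive center-to-center distances, in center order."""
    c = peakset.centers()
    if len(c) < 2:
        return np.array([], dtype=float)
    return np.diff(np.sort(c))


def ndr_width(peakset: PeakSet, model: FragmentSizeModel) -> NdrCall:
    """Size the NDR from the called -1 and +1 peaks.

    Width is the -1/+1 center separation minus the nucleosome footprint; a
    no-call (with reason) results if either flanking peak is missing.
    """
    up, down = peakset.get(-1), peakset.get(1)
    if up is None or down is None:
        missing = [lbl for lbl, p in ((-1, up), (1, down)) if p is None]
        return NdrCall(None, None, model.footprint,
                       reason=f"missing flanking peak(s): {missing}")
    return ndr_from_separation(down.center - up.center, model)


def ndr_from_separation(separation: float, model: FragmentSizeModel) -> NdrCall:
    """NDR width from a -1/+1 peak separation (bp)."""
    return NdrCall(float(separation), float(separation - model.footprint), model.footprint)


def occupancy_ratio(peakset: PeakSet, scale: str = "density") -> float:
    """Ratio of nucleosome density at the -1 peak to density at the +1 peak.

    The aggregate profile is log2(MNase/gDNA); on the default ``density``
    scale the ratio is taken between the underlying MNase/gDNA densities,
    ``2**(A(-1) - A(+1))``, so that it tracks relative occupancy directly.
    ``scale="log2"`` instead divides the smoothed log2 amplitudes.
    """
    up, down = peakset.get(-1), peakset.get(1)
    if up is None or down is None:
        raise ValueError("occupancy ratio requires both -1 and +1 peaks")
    if scale == "density":
        return float(2.0 ** (up.amplitude - down.amplitude))
    if scale == "log2":
        if down.amplitude == 0:
            raise ZeroDivisionError("+1 peak amplitude is zero")
        return float(up.amplitude / down.amplitude)
    raise ValueError(f"unknown scale {scale!r}")


def percent_reduction(ratio: float, reference_ratio: float) -> float:
    """Percent change of an occupancy ratio relative to a reference sample."""
    if reference_ratio <= 0:
        raise ValueError("reference ratio must be positive")
    return (1.0 - ratio / reference_ratio) * 100.0


def summary_dict(peakset: PeakSet, ndr: NdrCall | None = None) -> dict:
    """JSON-ready summary of peaks, spacings and the NDR call."""
    out = {
        "peaks": [
            {
                "label": p.label,
                "center": p.center,
                "amplitude": p.amplitude,
                "prominence": p.prominence,
            }
            for p in peakset.peaks
        ],
        "spacings": peak_spacings(peakset).tolist(),
    }
    if ndr is not None:
        out["ndr"] = {
            "separation": ndr.separation,
            "width": ndr.width,
            "footprint": ndr.footprint,
            "reason": ndr.reason,
        }
    return out
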