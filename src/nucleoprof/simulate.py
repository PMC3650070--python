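"""Synthetic MNase-chip experiments with known ground truth.

A population of ``n_cells`` cells is simulated per gene. Each configured
nucleosome template is present in a cell with probability ``occupancy``;
when present it protects a fragment of length ~ Normal(wrap_length,
fragment_length_sd) centered at the template position plus per-cell jitter
~ Normal(0, fuzziness), mirrored onto genomic coordinates for minus-strand
genes. Probe intensities model hybridization of the protected fragments to
a 50-mer tiling array: a fragment contributes its bp overlap with a probe
provided the overlap reaches ``min_hybridization_overlap`` (partial
duplexes wash off; threshold 0 reduces to pure overlap coverage, under
which total signal exactly equals total fragment-bp on the tile). A
uniform sheared-gDNA channel and log-normal multiplicative intensity noise
complete the two-channel observation model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import io as nio

__all__ = [
    "NucleosomeTemplate",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationResult",
    "simulate_experiment",
    "make_stage_config",
    "make_config",
    "expected_rel_profile",
    "expected_peaks",
    "STAGE_TEMPLATES",
]


@dataclass(frozen=True)
class NucleosomeTemplate:
    """A positioned nucleosome: TSS-relative center, occupancy, fuzziness.

    ``occupancy`` is the probability that a cell carries the nucleosome;
    ``fuzziness`` is the standard deviation (bp) of its per-cell center.
    """

    rel_center: float
    occupancy: float
    fuzziness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.fuzziness < 0:
            raise ValueError("fuzziness must be >= 0")


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic MNase-chip experiment."""

    genome_length: int
    genes: list[tuple[str, int, str]]
    group_templates: dict[str, list[NucleosomeTemplate]]
    gene_group: dict[str, str] | None = None
    n_cells: int = 2000
    wrap_length: float = 147.0
    fragment_length_sd: float = 6.0
    probe_length: int = 50
    probe_step: int = 20
    background_rate: float = 0.05
    channel_noise_sd: float = 0.10
    gdna_noise_sd: float = 0.05
    min_hybridization_overlap: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_step > self.probe_length:
            raise ValueError("probe_step must be <= probe_length")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("background_rate", "channel_noise_sd", "gdna_noise_sd",
                     "fragment_length_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        strands = {s for _, _, s in self.genes}
        if not strands.issubset({"+", "-"}):
            raise ValueError("gene strands must be '+' or '-'")
        if self.gene_group is None and len(self.group_templates) == 1:
            only = next(iter(self.group_templates))
            self.gene_group = {g: only for g, _, _ in self.genes}
        if self.gene_group is None:
            raise ValueError("gene_group mapping required with multiple template groups")
        margin = self.wrap_length / 2 + 4 * self.fragment_length_sd
        for gene_id, tss, strand in self.genes:
            group = self.gene_group[gene_id]
            for t in self.group_templates[group]:
                rel = t.rel_center if strand == "+" else -t.rel_center
                center = tss + rel
                reach = margin + 4 * t.fuzziness
                if center - reach < 0 or center + reach > self.genome_length:
                    raise ValueError(
                        f"template at rel {t.rel_center:+g} of gene {gene_id!r} "
                        f"extends beyond the genome bounds"
                    )

    def templates_for(self, gene_id: str) -> list[NucleosomeTemplate]:
        return self.group_templates[self.gene_group[gene_id]]


@dataclass
class SyntheticTruth:
    """Ground truth serialized beside the generated tables."""

    gene_templates: dict[str, list[NucleosomeTemplate]]
    expected_peak_centers: dict[str, list[float]]
    expected_peak_amplitudes: dict[str, list[float]]

    def to_json(self, path) -> None:
        payload = {
            "gene_templates": {
                g: [asdict(t) for t in ts] for g, ts in self.gene_templates.items()
            },
            "expected_peak_centers": self.expected_peak_centers,
            "expected_peak_amplitudes": self.expected_peak_amplitudes,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SimulationResult:
    probes: pd.DataFrame
    signals: pd.DataFrame
    tss: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        nio.write_probes(self.probes, os.path.join(outdir, "probes.tsv"))
        nio.write_signals(self.signals, os.path.join(outdir, "signals.tsv"))
        nio.write_tss(self.tss, os.path.join(outdir, "tss.bed"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def _hybridization_kernel(dist: np.ndarray, probe_length: float, frag_length: float,
                          min_overlap: float) -> np.ndarray:
    """Expected probe response vs probe-center-to-fragment-center distance."""
    ov = np.clip(np.minimum(probe_length, (frag_length + probe_length) / 2 - np.abs(dist)),
                 0.0, probe_length)
    if min_overlap > 0:
        ov = np.where(ov >= min_overlap, ov, 0.0)
    return ov


def expected_rel_profile(config: SimulationConfig, group: str,
                         flank: float = 600.0) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected probe response on the TSS-relative axis.

    Evaluates, on a 1 bp grid, the per-probe expected MNase signal (per
    cell, excluding background) for a probe centered at each relative
    position: the hybridization kernel convolved with each template's
    positional jitter, weighted by occupancy. Fragment-length variation is
    ignored here (it is small relative to the probe span).
    """
    x = np.arange(-flank, flank + 1.0)
    prof = np.zeros_like(x)
    for t in config.group_templates[group]:
        if t.fuzziness > 0:
            g = np.arange(-4 * t.fuzziness, 4 * t.fuzziness + 1.0)
            w = np.exp(-0.5 * (g / t.fuzziness) ** 2)
            w /= w.sum()
        else:
            g = np.array([0.0])
            w = np.array([1.0])
        for gi, wi in zip(g, w):
            d = np.abs(x - (t.rel_center + gi))
            prof += t.occupancy * wi * _hybridization_kernel(
                d, config.probe_length, config.wrap_length,
                config.min_hybridization_overlap
            )
    return x, prof


def expected_peaks(config: SimulationConfig, group: str, flank: float = 600.0,
                   min_prominence: float = 0.05) -> tuple[list[float], list[float]]:
    """Local maxima of the expected aggregate log2 profile for one gene group.

    These are the peaks the pipeline can resolve: templates closer than the
    hybridization kernel width merge and are reported as a single maximum.
    The profile is put on the same log2(MNase/gDNA) scale the peak caller
    sees (population coverage plus background over its own mean), so
    ``min_prominence`` matches the caller's default. Amplitudes are on that
    log2 scale.
    """
    from scipy.signal import find_peaks

    x, prof = expected_rel_profile(config, group, flank)
    background = config.background_rate * config.n_cells * config.probe_length
    intensity = config.n_cells * prof + background
    if intensity.max() <= 0:
        return [], []
    floor = intensity[intensity > 0].min()
    log2prof = np.log2(np.maximum(intensity, floor) / intensity.mean())
    idx, _ = find_peaks(log2prof, prominence=min_prominence)
    return [float(x[i]) for i in idx], [float(log2prof[i]) for i in idx]


def _sample_fragments(config: SimulationConfig, rng: np.random.Generator):
    """Sample protected fragments for every gene and cell; returns (start, end)."""
    starts, ends = [], []
    for gene_id, tss, strand in config.genes:
        for t in config.templates_for(gene_id):
            k = int(rng.binomial(config.n_cells, t.occupancy))
            if k == 0:
                continue
            jitter = rng.normal(0.0, t.fuzziness, size=k) if t.fuzziness > 0 else np.zeros(k)
            lengths = (
                rng.normal(config.wrap_length, config.fragment_length_sd, size=k)
                if config.fragment_length_sd > 0
                else np.full(k, config.wrap_length)
            )
            lengths = np.maximum(np.round(lengths), 1.0)
            rel = t.rel_center + jitter
            centers = tss + rel if strand == "+" else tss - rel
            s = np.round(centers - lengths / 2.0)
            starts.append(s)
            ends.append(s + lengths)
    if not starts:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(starts), np.concatenate(ends)


def _probe_signal(config: SimulationConfig, frag_start: np.ndarray,
                  frag_end: np.ndarray, n_probes: int) -> np.ndarray:
    """Accumulate thresholded fragment-probe overlap into per-probe signal."""
    signal = np.zeros(n_probes)
    if len(frag_start) == 0:
        return signal
    step, plen = config.probe_step, config.probe_length
    k_min = np.ceil((frag_start - plen + 1) / step).astype(np.int64)
    k_max = np.floor((frag_end - 1) / step).astype(np.int64)
    np.clip(k_min, 0, n_probes - 1, out=k_min)
    np.clip(k_max, -1, n_probes - 1, out=k_max)
    max_span = int(np.max(k_max - k_min)) + 1 if len(frag_start) else 0
    for j in range(max_span):
        k = k_min + j
        m = k <= k_max
        if not m.any():
            break
        ps = k[m] * step
        ov = np.minimum(frag_end[m], ps + plen) - np.maximum(frag_start[m], ps)
        if config.min_hybridization_overlap > 0:
            ov = np.where(ov >= config.min_hybridization_overlap, ov, 0.0)
        np.add.at(signal, k[m], ov)
    return signal


def simulate_experiment(
    config: SimulationConfig,
    n_replicates: int = 2,
    sample_id: str = "sample",
    chrom: str = "chrSim",
) -> SimulationResult:
    """Generate a complete synthetic experiment (deterministic given seed).

    One cell population is sampled per gene; each replicate re-noises the
    same realized fragment coverage with its own sub-seed, mimicking two
    hybridizations of one digestion series.
    """
    rng = np.random.default_rng(config.seed)
    frag_rng, *noise_rngs = rng.spawn(1 + n_replicates)

    n_probes = (config.genome_length - config.probe_length) // config.probe_step + 1
    probe_starts = np.arange(n_probes) * config.probe_step
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i:06d}" for i in range(n_probes)],
            "chrom": chrom,
            "start": probe_starts,
            "end": probe_starts + config.probe_length,
        }
    )
    probes["center"] = (probes["start"] + probes["end"]) / 2.0

    frag_start, frag_end = _sample_fragments(config, frag_rng)
    coverage = _probe_signal(config, frag_start, frag_end, n_probes)
    background = config.background_rate * config.n_cells * config.probe_length
    expected = coverage + background
    gdna_expected = float(expected.mean()) if expected.mean() > 0 else 1.0

    tables = []
    for r, nrng in enumerate(noise_rngs, start=1):
        mnase = expected * (
            nrng.lognormal(0.0, config.channel_noise_sd, size=n_probes)
            if config.channel_noise_sd > 0 else 1.0
        )
        gdna = gdna_expected * (
            nrng.lognormal(0.0, config.gdna_noise_sd, size=n_probes)
            if config.gdna_noise_sd > 0 else np.ones(n_probes)
        )
        tables.append(
            pd.DataFrame(
                {
                    "probe_id": probes["probe_id"],
                    "mnase": mnase,
                    "gdna": gdna,
                    "replicate_id": f"rep{r}",
                    "sample_id": sample_id,
                }
            )
        )
    signals = pd.concat(tables, ignore_index=True)

    tss = pd.DataFrame(
        [(g, chrom, t, s) for g, t, s in config.genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    )

    centers_by_group = {}
    amps_by_group = {}
    for group in config.group_templates:
        c, a = expected_peaks(config, group)
        centers_by_group[group] = c
        amps_by_group[group] = a
    truth = SyntheticTruth(
        gene_templates={g: config.templates_for(g) for g, _, _ in config.genes},
        expected_peak_centers=centers_by_group,
        expected_peak_amplitudes=amps_by_group,
    )
    return SimulationResult(probes, signals, tss, truth, config)


# TSS-relative template sets for the three organizational stages seen across
# the early-embryo time course: disordered chromatin before genome
# activation, partial downstream positioning (+1/+2/+3 at +60/+260/+480),
# and the mature promoter architecture (-3..-2..-1 upstream, an NDR-spanning
# gap, and an elevated +1) at the latest stage.
STAGE_TEMPLATES: dict[str, list[NucleosomeTemplate]] = {
    "disordered": [
        NucleosomeTemplate(rel, 0.15, 160.0) for rel in range(-900, 901, 180)
    ],
    "partial": [
        NucleosomeTemplate(60.0, 0.45, 30.0),
        NucleosomeTemplate(260.0, 0.45, 30.0),
        NucleosomeTemplate(480.0, 0.45, 30.0),
    ],
    "ordered": [
        NucleosomeTemplate(-450.0, 0.50, 20.0),
        NucleosomeTemplate(-290.0, 0.50, 20.0),
        NucleosomeTemplate(-170.0, 0.50, 20.0),
        NucleosomeTemplate(115.0, 0.80, 20.0),
        NucleosomeTemplate(250.0, 0.60, 20.0),
    ],
}

_GENE_SPACING = 3000
# Offset leaves room for the widest stage templates (+-900 plus 4 sd of
# fuzziness); the trailing 3 keeps TSS-relative probe centers off the
# half-open window boundaries of the default 30/10 grid.
_GENE_OFFSET = 1703


def _default_genes(n_genes: int) -> tuple[list[tuple[str, int, str]], int]:
    # The per-gene phase term staggers TSSs relative to the 20 bp probe
    # lattice (7 is coprime to 20, so phases cycle through all residues);
    # real promoters sit at arbitrary phases, and a shared phase would
    # alias the probe lattice into systematic window-to-window wiggles.
    genes = [
        (
            f"g{i:03d}",
            _GENE_OFFSET + i * _GENE_SPACING + (i * 7) % 20,
            "+" if i % 2 == 0 else "-",
        )
        for i in range(n_genes)
    ]
    genome_length = n_genes * _GENE_SPACING + 2 * _GENE_OFFSET
    return genes, genome_length


def make_config(
    templates: list[NucleosomeTemplate],
    group_name: str = "all",
    n_genes: int = 37,
    n_cells: int = 2000,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Config with one template set shared by ``n_genes`` evenly spaced genes.

    Genes alternate strand; keyword overrides pass through to
    :class:`SimulationConfig`.
    """
    genes, genome_length = _default_genes(n_genes)
    return SimulationConfig(
        genome_length=genome_length,
        genes=genes,
        group_templates={group_name: list(templates)},
        n_cells=n_cells,
        seed=seed,
        **overrides,
    )


def make_stage_config(
    stage: str, n_genes: int = 37, n_cells: int = 2000, seed: int = 0, **overrides
) -> SimulationConfig:
    """Preset configs for the three developmental organization stages.

    ``disordered``: high-fuzziness (160 bp), low-occupancy nucleosomes tiled
    well beyond the profiled flank, so the expected aggregate profile is
    flat. ``partial``: moderately occupied +1/+2/+3 nucleosomes at
    +60/+260/+480. ``ordered``: the five-nucleosome promoter architecture at
    -450/-290/-170/+115/+250 with an elevated +1 and the NDR-spanning gap.
    """
    if stage not in STAGE_TEMPLATES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGE_TEMPLATES)}")
    return make_config(
        STAGE_TEMPLATES[stage], group_name=stage, n_genes=n_genes,
        n_cells=n_cells, seed=seed, **overrides
    )
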