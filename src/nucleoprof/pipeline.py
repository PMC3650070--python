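"""End-to-end orchestration: tables in, report bundle out.

`RunConfig` collects every path and stage parameter (defaults are the
study's: 30/10 bp windows over +-600 bp, lowess f = 0.05, 160 bp footprint,
alpha = 0.05); `run_pipeline` executes profile -> peaks -> NDR -> ratios ->
comparison for every sample in the signal table and writes TSV tracks plus
a versioned JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import io as nio
from . import peaks as _peaks
from .model import GroupComparison, NucleosomeProfile

logger = logging.getLogger(__name__)

SUMMARY_VERSION = 1

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    probes: str = ""
    signals: str = ""
    tss: str = ""
    groups: str | None = None
    out_dir: str = "nucleoprof_out"
    group_a: str | None = None
    group_b: str | None = None
    gene_set: str | None = None  # restrict profiles to one named group
    window: float = 30.0
    step: float = 10.0
    flank: float = 600.0
    span: float = 0.05
    min_prominence: float = 0.05
    min_separation: float = 100.0
    footprint: float = 160.0
    alpha: float = 0.05
    seed: int = 17
    per_gene_mean: bool = False
    median_center: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(path: str, what: str) -> None:
    if not path or not os.path.exists(path):
        raise FileNotFoundError(f"{what} file not found: {path!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Per sample: windowed and smoothed aggregate tracks (TSV), labeled peak
    table, NDR call and -1/+1 occupancy ratio; optionally a windowwise
    rank-sum comparison between two named gene groups. Everything is also
    collected into ``summary.json`` (stable, versioned keys), which is
    returned.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("nucleoprof").addHandler(handler)
    try:
        return _run(config)
    finally:
        logging.getLogger("nucleoprof").removeHandler(handler)
        handler.close()


def _run(config: RunConfig) -> dict:
    _require(config.probes, "probe table")
    _require(config.signals, "signal table")
    _require(config.tss, "TSS annotation")
    logger.info("reading inputs")
    probes = nio.read_probes(config.probes)
    signals = nio.read_signals(config.signals)
    tss = nio.read_tss(config.tss)
    groups = None
    if config.groups:
        _require(config.groups, "gene-group table")
        groups = nio.read_groups(config.groups)

    gene_subset = None
    if config.gene_set:
        if groups is None or config.gene_set not in groups:
            raise ValueError(
                f"gene_set {config.gene_set!r} not found in the group table"
            )
        gene_subset = groups[config.gene_set]

    fragment_model = _peaks.FragmentSizeModel(footprint=config.footprint)
    summary: dict = {
        "version": SUMMARY_VERSION,
        "effective_config": config.to_dict(),
        "samples": {},
    }

    sample_ids = sorted(signals["sample_id"].unique())
    rel_by_sample = {}
    for sample in sample_ids:
        logger.info("profiling sample %s", sample)
        model = NucleosomeProfile.from_tables(
            probes,
            signals,
            tss,
            sample_id=sample,
            median_center=config.median_center,
            genes=gene_subset,
            window=config.window,
            step=config.step,
            flank=config.flank,
            span_f=config.span,
            per_gene_mean=config.per_gene_mean,
        )
        rel_by_sample[sample] = model.rel_signals
        result = model.fit(
            min_prominence=config.min_prominence,
            min_separation=config.min_separation,
            fragment_model=fragment_model,
        )
        prefix = os.path.join(config.out_dir, f"{sample}")
        result.window_track.to_tsv(prefix + ".windows.tsv")
        result.smooth_track.to_tsv(prefix + ".smooth.tsv")
        result.peaks.to_tsv(prefix + ".peaks.tsv")
        entry = _peaks.summary_dict(result.peaks, result.ndr)
        try:
            entry["occupancy_ratio"] = result.occupancy_ratio()
        except ValueError:
            entry["occupancy_ratio"] = None
        summary["samples"][sample] = entry

    if groups is not None and config.group_a and config.group_b:
        logger.info("comparing %r vs %r", config.group_a, config.group_b)
        for name in (config.group_a, config.group_b):
            if name not in groups:
                raise ValueError(f"group {name!r} not in the group table")
        comp_summaries = {}
        for sample in sample_ids:
            comparison = GroupComparison(
                rel_by_sample[sample],
                groups[config.group_a],
                groups[config.group_b],
                window=config.window,
                step=config.step,
                flank=config.flank,
            ).fit(alpha=config.alpha)
            comparison.track.to_tsv(
                os.path.join(config.out_dir, f"{sample}.wilcoxon.tsv")
            )
            comp_summaries[sample] = {
                "group_a": config.group_a,
                "group_b": config.group_b,
                "alpha": config.alpha,
                "n_significant": int(comparison.track.significant.sum()),
                "significant_centers": comparison.significant_windows().tolist(),
            }
        summary["comparison"] = comp_summaries

    out_json = os.path.join(config.out_dir, "summary.json")
    with open(out_json, "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("wrote %s", out_json)
    return summary
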