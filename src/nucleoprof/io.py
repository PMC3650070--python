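"""Reading and writing of probe, signal, TSS and gene-group tables.

All genomic coordinates are 0-based, half-open (BED convention). Probe
tables, two-channel signal tables and gene-group tables are plain
tab-separated text with a header line; TSS annotations are BED6. Missing
values are written as ``.``.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ParseError",
    "read_probes",
    "write_probes",
    "read_tss",
    "write_tss",
    "read_signals",
    "write_signals",
    "read_groups",
    "write_groups",
    "load_hox_groups",
    "HOX_GROUP_NAMES",
]


class ParseError(ValueError):
    """Raised when an input table cannot be parsed or fails validation."""


PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]
SIGNAL_COLUMNS = ["probe_id", "mnase", "gdna", "replicate_id", "sample_id"]


def read_probes(path) -> pd.DataFrame:
    """Read a tiled-probe definition table.

    Parameters
    ----------
    path
        Tab-separated file with header columns ``probe_id``, ``chrom``,
        ``start``, ``end`` (0-based half-open intervals).

    Returns
    -------
    DataFrame with columns ``probe_id, chrom, start, end, center`` in file
    order; ``center`` is the (possibly half-integral) interval midpoint.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(PROBE_COLUMNS)] != PROBE_COLUMNS:
            raise ParseError(
                f"{path}: expected header {PROBE_COLUMNS}, got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            probe_id, chrom, start_s, end_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: probe {probe_id!r} has end <= start ({end} <= {start})"
                )
            rows.append((probe_id, chrom, start, end))
    df = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["center"] = (df["start"] + df["end"]) / 2.0
    return df


def write_probes(probes: pd.DataFrame, path) -> None:
    probes[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")


def read_tss(path) -> pd.DataFrame:
    """Read one-TSS-per-gene annotations from a BED6 file.

    The TSS is the first transcribed base: the ``start`` field on the plus
    strand and ``end - 1`` on the minus strand. Duplicate gene ids and
    strands outside ``{+,-}`` are rejected.

    Returns
    -------
    DataFrame with columns ``gene_id, chrom, tss, strand``.
    """
    rows = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields")
            chrom, start_s, end_s, gene_id, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start for gene {gene_id!r}")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            tss = start if strand == "+" else end - 1
            rows.append((gene_id, chrom, tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def write_tss(tss: pd.DataFrame, path) -> None:
    """Write TSS annotations as BED6 (single-base intervals at the TSS)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for row in tss.itertuples(index=False):
            if row.strand == "+":
                start, end = row.tss, row.tss + 1
            else:
                start, end = row.tss, row.tss + 1
            fh.write(f"{row.chrom}\t{start}\t{end}\t{row.gene_id}\t0\t{row.strand}\n")


def read_signals(path) -> pd.DataFrame:
    """Read a long-format two-channel signal table.

    Columns: ``probe_id, mnase, gdna, replicate_id, sample_id``. Intensities
    must be strictly positive (required before taking logs) and
    (probe_id, replicate_id, sample_id) must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "replicate_id": str, "sample_id": str})
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = df[(df["mnase"] <= 0) | (df["gdna"] <= 0)]
    if len(bad):
        raise ParseError(
            f"{path}: non-positive intensity for probe_id "
            f"{bad['probe_id'].iloc[0]!r} (and {len(bad) - 1} more)"
        )
    dup = df.duplicated(subset=["probe_id", "replicate_id", "sample_id"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (probe_id, replicate_id, sample_id) rows")
    return df[SIGNAL_COLUMNS + [c for c in df.columns if c not in SIGNAL_COLUMNS]]


def write_signals(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index=False, na_rep=".")


def read_groups(path) -> dict[str, set[str]]:
    """Read a gene-group membership table (columns ``group``, ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"group", "gene_id"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns 'group' and 'gene_id'")
    groups: dict[str, set[str]] = {}
    for group, sub in df.groupby("group", sort=False):
        groups[str(group)] = set(sub["gene_id"])
    return groups


def write_groups(groups: dict[str, set[str]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("group\tgene_id\n")
        for name, members in groups.items():
            for gene in sorted(members):
                fh.write(f"{name}\t{gene}\n")


# Expression groups of the 37 zebrafish hox genes in the study (one TSS per
# gene). Column semantics: wild-type expression status at 9 hpf, retinoic
# acid response at 6 hpf, and the RA-induced-but-not-endogenously-expressed
# set ("RA-only").
HOX_GROUP_NAMES = (
    "9 hpf WT non-expressed",
    "9 hf WT expressed",
    "6 hpf RA treated uninduced",
    "6 hpf RA treated induced",
    "RA-only",
)

_HOX_NON_EXPRESSED = """
hoxa4a hoxa5a hoxa9a hoxa11a hoxa13a hoxa9b hoxa11b hoxa13b
hoxb2a hoxb4a hoxb5a hoxb6a hoxb9a hoxb13a hoxb8b
hoxc1a hoxc4a hoxc5a hoxc6a hoxc10a hoxc11a hoxc12a hoxc13a hoxc6b hoxc12b
hoxd4a hoxd9a hoxd10a hoxd11a hoxd12a hoxd13a
""".split()

_HOX_EXPRESSED = "hoxb1a hoxb7a hoxb5b hoxb6b hoxc8a hoxc9a".split()

_HOX_RA_UNINDUCED = """
hoxa9a hoxa11a hoxa13a hoxa9b hoxa11b hoxa13b
hoxb2a hoxb4a hoxb6a hoxb7a hoxb9a hoxb13a hoxb8b
hoxc6a hoxc8a hoxc9a hoxc10a hoxc11a hoxc12a hoxc13a hoxc6b hoxc12b
hoxd4a hoxd9a hoxd10a hoxd11a hoxd12a hoxd13a
""".split()

_HOX_RA_INDUCED = "hoxa4a hoxa5a hoxb1a hoxb5a hoxb5b hoxb6b hoxc1a hoxc4a hoxc5a".split()

_HOX_RA_ONLY = "hoxa4a hoxa5a hoxb5a hoxc1a hoxc4a hoxc5a".split()


def load_hox_groups() -> dict[str, set[str]]:
    """Return the packaged hox expression-group table.

    Five groups keyed by the study's column names (`HOX_GROUP_NAMES`); a
    gene may appear in several groups. The expressed and non-expressed
    groups partition the 37 genes of the study.
    """
    return {
        HOX_GROUP_NAMES[0]: set(_HOX_NON_EXPRESSED),
        HOX_GROUP_NAMES[1]: set(_HOX_EXPRESSED),
        HOX_GROUP_NAMES[2]: set(_HOX_RA_UNINDUCED),
        HOX_GROUP_NAMES[3]: set(_HOX_RA_INDUCED),
        HOX_GROUP_NAMES[4]: set(_HOX_RA_ONLY),
    }
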