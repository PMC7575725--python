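"""Expression-matrix and annotation I/O, probe collapsing, lncRNA detection.

All tabular formats are plain TSV.  An expression table has one header row
of sample identifiers and one leading identifier column (probes or genes in
rows by default); ``NA`` or an empty cell marks a missing value.  Probe
annotation tables carry ``probe_id``, ``gene_symbol`` and ``description``
columns; multi-gene probes use the Affymetrix ``" /// "`` separator inside
``gene_symbol``.

In memory, matrices are :class:`pandas.DataFrame` objects (rows = probes or
gene symbols, columns = samples) and a design is a :class:`pandas.Series`
mapping sample id to a group label in ``{"case", "control"}``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidDesignError,
    InvalidInputError,
    ParseError,
    PipelineError,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "read_design",
    "collapse_probes",
    "CollapseReport",
    "detect_lncrna_probes",
]

#: String written/recognised for a missing expression value.
NA_TOKEN = "NA"

MULTI_SYMBOL_SEP = "///"


def read_expression_table(path, orientation: str = "genes_in_rows") -> pd.DataFrame:
    """Read a TSV expression matrix into a probes/genes x samples DataFrame.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file: header row of sample ids, identifier column
        first.  ``NA`` or empty cells become missing values.
    orientation : {"genes_in_rows", "samples_in_rows"}
        With ``samples_in_rows`` the parsed table is transposed so the
        returned frame is always features x samples.

    Raises
    ------
    ParseError
        On ragged rows, duplicate identifiers or non-numeric cells; the
        message cites the 1-based line number.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file", line=1) from None
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dup = _first_duplicate(sample_ids)
            raise ParseError(f"{path}: duplicate column identifier {dup!r}", line=1)
        n_cols = len(header)
        row_ids: list[str] = []
        seen: set[str] = set()
        values: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue  # trailing blank line
            if len(row) != n_cols:
                raise ParseError(
                    f"{path}: expected {n_cols} fields, found {len(row)}",
                    line=lineno,
                )
            rid = row[0]
            if rid in seen:
                raise ParseError(f"{path}: duplicate row identifier {rid!r}", line=lineno)
            seen.add(rid)
            row_ids.append(rid)
            parsed = []
            for cell in row[1:]:
                if cell == NA_TOKEN or cell == "":
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r}", line=lineno
                    ) from None
            values.append(parsed)
    df = pd.DataFrame(values, index=row_ids, columns=sample_ids, dtype=float)
    if orientation == "samples_in_rows":
        df = df.T
        if df.columns.duplicated().any():
            raise ParseError(f"{path}: duplicate sample identifiers after transpose")
    return df


def write_expression_table(matrix: pd.DataFrame, path, id_label: str = "id") -> None:
    """Write a features x samples matrix as TSV, ``NA`` for missing values."""
    out = matrix.copy()
    out.index.name = id_label
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns probe_id, gene_symbol, description."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_symbol", "description"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}", line=1)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicate probe_id {dup!r}")
    return df.set_index("probe_id")


def read_design(path) -> pd.Series:
    """Read a design TSV (columns sample_id, group) into a sample -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ParseError(f"{path}: design needs columns sample_id, group", line=1)
    design = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    validate_design(design)
    return design


def validate_design(design: pd.Series) -> None:
    labels = set(design.unique())
    if not labels <= {"case", "control"}:
        raise InvalidDesignError(
            f"group labels must be 'case'/'control', found {sorted(labels)}"
        )
    counts = design.value_counts()
    for grp in ("case", "control"):
        if counts.get(grp, 0) == 0:
            raise InvalidDesignError(f"design has no {grp!r} samples")


@dataclass
class CollapseReport:
    """Bookkeeping of the probe -> gene collapse."""

    n_probes_in: int = 0
    n_dropped_multi_symbol: int = 0
    n_dropped_unannotated: int = 0
    n_genes_out: int = 0
    multi_probe_genes: list = field(default_factory=list)


def collapse_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    scale: str = "log2",
) -> tuple[pd.DataFrame, CollapseReport]:
    """Collapse a probe-level matrix to gene symbols.

    Probes annotated to multiple symbols (``" /// "``) are discarded, as are
    unannotated probes; the remaining probes are grouped by symbol and
    averaged per sample.  Averaging is an arithmetic mean of the (log2)
    values by default; ``scale="linear"`` averages ``2**value`` and returns
    to log2, emulating averaging of raw MAS5 signals.

    A gene's sample value is missing only when every contributing probe is
    missing for that sample.
    """
    if scale not in ("log2", "linear"):
        raise InvalidInputError(f"unknown averaging scale {scale!r}")
    report = CollapseReport(n_probes_in=len(matrix))
    symbols = annotation["gene_symbol"].reindex(matrix.index)

    unannotated = symbols.isna() | (symbols.str.strip() == "")
    multi = symbols.notna() & symbols.str.contains(MULTI_SYMBOL_SEP, regex=False)
    keep = ~(unannotated | multi)
    report.n_dropped_unannotated = int(unannotated.sum())
    report.n_dropped_multi_symbol = int(multi.sum())
    if not keep.any():
        raise PipelineError("probe collapse dropped every probe")

    sub = matrix.loc[keep]
    sym = symbols[keep].str.strip()
    if scale == "linear":
        grouped = np.log2(np.power(2.0, sub).groupby(sym).mean())
    else:
        grouped = sub.groupby(sym).mean()
    # groupby sorts symbols lexicographically: a deterministic, reproducible order
    sizes = sub.groupby(sym).size()
    report.multi_probe_genes = sizes.index[sizes > 1].tolist()
    report.n_genes_out = len(grouped)
    grouped.index.name = "gene"
    return grouped, report


def read_series_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix text file (already downloaded, uncompressed).

    Returns ``(matrix, sample_meta)``: the probe x sample expression table
    from the ``!series_matrix_table_begin`` block, and a per-sample
    metadata frame (one row per GSM accession, one column per
    ``!Sample_*`` header) useful for assembling a design file.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = [v.strip('"') for v in line.split("\t")]
                meta.setdefault(key.lstrip("!"), vals)
    if not table_lines:
        raise ParseError(f"{path}: no series_matrix table block found")
    header = [v.strip('"') for v in table_lines[0].split("\t")]
    rows = []
    for ln in table_lines[1:]:
        if not ln:
            continue
        fields = [v.strip('"') for v in ln.split("\t")]
        rows.append(fields)
    matrix = pd.DataFrame(rows, columns=header).set_index(header[0])
    matrix = matrix.replace({"": np.nan, "null": np.nan, NA_TOKEN: np.nan}).astype(float)
    matrix.index.name = "probe"
    sample_meta = pd.DataFrame(meta)
    if "Sample_geo_accession" in sample_meta.columns:
        sample_meta = sample_meta.set_index("Sample_geo_accession")
    return matrix, sample_meta


def detect_lncrna_probes(
    annotation: pd.DataFrame, keyword: str = "non-coding"
) -> set[str]:
    """Gene symbols whose probe description contains ``keyword``.

    Matching is a case-insensitive substring test on the description text
    (hyphen variants such as ``"noncoding"`` are deliberately not
    expanded).  Probes without a usable single-gene symbol are ignored;
    the result is deduplicated by symbol.
    """
    if not keyword:
        raise InvalidInputError("keyword must be non-empty")
    desc = annotation["description"].fillna("")
    hit = desc.str.contains(keyword, case=False, regex=False)
    symbols = annotation.loc[hit, "gene_symbol"].str.strip()
    usable = (symbols != "") & ~symbols.str.contains(MULTI_SYMBOL_SEP, regex=False)
    return set(symbols[usable])


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None
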