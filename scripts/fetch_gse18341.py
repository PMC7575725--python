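#!/usr/bin/env python
"""Opt-in GEO accession harness (requires network; never run by the tests).

Downloads the GSE18341 series matrix and the GPL1261 annotation, converts
them to the package's TSV formats, and reruns the array stages: probe
collapse (multi-symbol probes dropped, per-gene mean), differential
expression at the standard thresholds (|FC| > 1.5, BH q < 0.05), and the
Malat1 seed-correlation screen (r > 0.5).  The study used 8 ALI and 8
normal arrays out of the series' 32; pass ``--samples`` with one GSM
accession + group label per line (tab-separated) to select them.

Usage::

    python scripts/fetch_gse18341.py --workdir scratch/gse18341 \
        --samples samples.tsv [--log2]

Annotation snapshots drift over time, so the derived counts may deviate
from any fixed publication; the per-stage tables are written to the work
directory for inspection.
"""

from __future__ import annotations

import argparse
import gzip
import sys
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

import cernascreen as cs

SERIES_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE18nnn/GSE18341/matrix/"
    "GSE18341_series_matrix.txt.gz"
)
PLATFORM_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/platforms/GPL1nnn/GPL1261/annot/"
    "GPL1261.annot.gz"
)


def fetch(url: str, dest: Path) -> Path:
    if dest.exists():
        return dest
    print(f"downloading {url}", file=sys.stderr)
    urllib.request.urlretrieve(url, dest)
    return dest


def parse_platform_annot(path: Path) -> pd.DataFrame:
    """GPL .annot table -> probe_id / gene_symbol / description frame."""
    with gzip.open(path, "rt", errors="replace") as fh:
        lines = fh.readlines()
    start = next(
        i for i, ln in enumerate(lines) if ln.startswith("!platform_table_begin")
    )
    end = next(i for i, ln in enumerate(lines) if ln.startswith("!platform_table_end"))
    rows = [ln.rstrip("\n").split("\t") for ln in lines[start + 1 : end]]
    table = pd.DataFrame(rows[1:], columns=rows[0])
    out = pd.DataFrame(
        {
            "probe_id": table["ID"],
            "gene_symbol": table.get("Gene symbol", ""),
            "description": table.get("Gene title", ""),
        }
    )
    return out.set_index("probe_id")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, required=True)
    parser.add_argument(
        "--samples",
        type=Path,
        help="TSV of GSM accession and group (case/control), no header; "
        "defaults to using every sample whose title mentions LPS as case",
    )
    parser.add_argument(
        "--log2", action="store_true",
        help="log2-transform the series values (use when the matrix is linear MAS5 signal)",
    )
    parser.add_argument("--seed-gene", default="Malat1")
    args = parser.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    series_gz = fetch(SERIES_URL, args.workdir / "series_matrix.txt.gz")
    series_txt = args.workdir / "series_matrix.txt"
    if not series_txt.exists():
        series_txt.write_text(gzip.open(series_gz, "rt", errors="replace").read())
    matrix, meta = cs.read_series_matrix(series_txt)

    annot = parse_platform_annot(fetch(PLATFORM_URL, args.workdir / "gpl1261.annot.gz"))

    if args.samples:
        sel = pd.read_csv(args.samples, sep="\t", header=None, names=["gsm", "group"])
        design = pd.Series(sel["group"].values, index=sel["gsm"].values)
    else:
        titles = meta["Sample_title"].str.lower()
        design = pd.Series(
            np.where(titles.str.contains("lps"), "case", "control"), index=meta.index
        )
        print("no --samples given; inferred design from titles:", file=sys.stderr)
        print(design.to_string(), file=sys.stderr)
    matrix = matrix[design.index]
    if args.log2:
        matrix = np.log2(matrix.clip(lower=1.0))

    collapsed, report = cs.collapse_probes(matrix, annot)
    print(
        f"probes in: {report.n_probes_in}  multi-symbol dropped: "
        f"{report.n_dropped_multi_symbol}  unannotated dropped: "
        f"{report.n_dropped_unannotated}  genes out: {report.n_genes_out}"
    )
    lncrnas = cs.detect_lncrna_probes(annot)
    print(f"lncRNA keyword hits: {len(lncrnas)}")

    de = cs.DifferentialExpression.from_preset(collapsed, design, "methods").fit()
    print(de.summary())
    de.table.to_csv(args.workdir / "de.tsv", sep="\t")

    corr = cs.seed_correlation_screen(collapsed, args.seed_gene)
    print(corr.summary())
    corr.table.to_csv(args.workdir / "corr.tsv", sep="\t")


if __name__ == "__main__":
    main()
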