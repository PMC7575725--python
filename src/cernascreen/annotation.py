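"""Tissue-specific gene sets from keyword search over GO term names.

A gene is tissue-specific (in the loose, screening sense used here) when it
is annotated to at least one ontology term whose *name* contains the tissue
keyword.  Matching is a case-insensitive substring test by default, which
mirrors a naive keyword search of an annotation snapshot; whole-word
matching is available for stricter queries.  No ontology-graph traversal is
performed: the annotation table is taken at face value.
"""

from __future__ import annotations

import re

import pandas as pd

from .errors import InvalidInputError, ParseError

__all__ = ["read_annotation_table", "tissue_gene_set", "gaf_to_annotation_table"]


def read_annotation_table(path) -> pd.DataFrame:
    """Read a gene-to-term TSV with columns ``gene`` and ``term_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "term_name"} <= set(df.columns):
        raise ParseError(f"{path}: annotation needs columns gene, term_name", line=1)
    df = df[(df["gene"] != "") & (df["term_name"] != "")]
    return df.drop_duplicates(ignore_index=True)


def tissue_gene_set(
    annotations: pd.DataFrame, keyword: str = "lung", whole_word: bool = False
) -> set[str]:
    """Genes annotated to >= 1 term whose name contains ``keyword``.

    Parameters
    ----------
    annotations : pandas.DataFrame
        Columns ``gene`` and ``term_name``.
    keyword : str
        Case-insensitive search string (default "lung").
    whole_word : bool
        Require the keyword to appear as a whole word rather than any
        substring (guards against accidental matches inside longer words).
    """
    if not keyword:
        raise InvalidInputError("keyword must be non-empty")
    if annotations.empty:
        raise InvalidInputError("annotation table is empty")
    names = annotations["term_name"]
    if whole_word:
        pat = re.compile(rf"\b{re.escape(keyword)}\b", re.IGNORECASE)
        hit = names.str.contains(pat)
    else:
        hit = names.str.contains(keyword, case=False, regex=False)
    return set(annotations.loc[hit, "gene"])


def gaf_to_annotation_table(gaf_path, term_names: dict[str, str]) -> pd.DataFrame:
    """Convert a GAF 2.x association file to the two-column annotation form.

    Only the object symbol (column 3) and GO id (column 5) are used; term
    names come from the supplied ``term_names`` mapping (GO id -> name).
    Associations whose GO id has no known name are dropped.
    """
    rows = []
    with open(gaf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            symbol, go_id = fields[2], fields[4]
            name = term_names.get(go_id)
            if symbol and name:
                rows.append((symbol, name))
    df = pd.DataFrame(rows, columns=["gene", "term_name"])
    return df.drop_duplicates(ignore_index=True)
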