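"""Shared miRNA-target enrichment against a seed lncRNA.

Under the ceRNA hypothesis, a transcript that shares an unexpectedly large
fraction of its miRNA interactors with a seed lncRNA is a candidate
competing RNA.  This module builds per-RNA miRNA target sets from a generic
RNA-RNA interaction table (RNAinter-style TSV), tests each gene's overlap
with the seed's set against the hypergeometric null (draws without
replacement from the observed miRNA universe), and lists the bridging
miRNAs behind each overlap.

Universe convention: ``N`` is the number of distinct miRNAs appearing in
any retained interaction row.  This is the least arbitrary choice
derivable from the input alone; no external miRNA catalogue is consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyIndexError, InvalidInputError, ParseError
from .stats import HypergeomParams, benjamini_hochberg, hypergeom_upper_tail

__all__ = [
    "read_interaction_table",
    "TargetSetIndex",
    "SharedTargetResult",
    "SharedTargetEnrichment",
    "EnrichmentResults",
    "shared_mirna_test",
    "cerna_screen_all",
    "bridging_mirnas",
]

INTERACTION_COLUMNS = ["rna1", "rna1_category", "rna2", "rna2_category", "score"]
MIRNA_CATEGORY = "miRNA"


def read_interaction_table(path) -> pd.DataFrame:
    """Read an interaction TSV (rna1, rna1_category, rna2, rna2_category, score).

    The score column may be empty.  Fully duplicate rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(INTERACTION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing interaction columns {sorted(missing)}", line=1)
    if "score" not in df.columns:
        df["score"] = ""
    df["score"] = pd.to_numeric(df["score"].replace("", np.nan), errors="raise")
    return df.drop_duplicates(ignore_index=True)


class TargetSetIndex:
    """Per-RNA sets of interacting miRNAs plus the miRNA universe.

    Interactions are treated as unordered pairs: a row in either column
    order contributes the same edge.  miRNA-miRNA rows never populate a
    target set but their members still join the universe.  Identifier
    matching is case-sensitive exact by default (``casefold=True`` lowers
    everything on the way in).
    """

    def __init__(
        self,
        targets: dict[str, set[str]],
        universe: set[str],
        pair_scores: dict[tuple[str, str], float] | None = None,
    ):
        for rna, s in targets.items():
            if not s <= universe:
                raise InvalidInputError(f"target set of {rna!r} escapes the universe")
        self.targets = targets
        self.universe = universe
        self.pair_scores = pair_scores or {}

    @classmethod
    def from_table(cls, table: pd.DataFrame, casefold: bool = False) -> "TargetSetIndex":
        """Build the index from a parsed interaction table.

        Raises
        ------
        EmptyIndexError
            If no row involves a miRNA.
        """
        targets: dict[str, set[str]] = {}
        universe: set[str] = set()
        scores: dict[tuple[str, str], list[float]] = {}
        fold = (lambda s: s.lower()) if casefold else (lambda s: s)
        for row in table.itertuples(index=False):
            a, ca = fold(row.rna1), row.rna1_category
            b, cb = fold(row.rna2), row.rna2_category
            score = getattr(row, "score", np.nan)
            a_mir = ca == MIRNA_CATEGORY
            b_mir = cb == MIRNA_CATEGORY
            if a_mir:
                universe.add(a)
            if b_mir:
                universe.add(b)
            if a_mir == b_mir:
                continue  # miRNA-miRNA or RNA-RNA rows carry no target edge
            rna, mir = (b, a) if a_mir else (a, b)
            targets.setdefault(rna, set()).add(mir)
            if score is not None and not (isinstance(score, float) and np.isnan(score)):
                scores.setdefault((rna, mir), []).append(float(score))
        if not universe:
            raise EmptyIndexError("interaction table has no miRNA-involving rows")
        pair_scores = {k: float(np.mean(v)) for k, v in scores.items()}
        return cls(targets, universe, pair_scores)

    def target_set(self, rna_id: str) -> set[str]:
        return self.targets.get(rna_id, set())

    def __contains__(self, rna_id: str) -> bool:
        return rna_id in self.targets

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class SharedTargetResult:
    """Hypergeometric overlap of one gene's miRNA set with the seed's."""

    gene: str
    k: int
    K: int
    n: int
    N: int
    p: float
    shared: tuple[str, ...]
    indexed: bool = True

    def params(self) -> HypergeomParams:
        return HypergeomParams(N=self.N, K=self.K, n=self.n, k=self.k)


def _seed_set(index: TargetSetIndex, seed_id: str) -> set[str]:
    seed = index.target_set(seed_id)
    if not seed:
        raise InvalidInputError(f"seed {seed_id!r} absent from index or has no targets")
    return seed


def shared_mirna_test(
    index: TargetSetIndex, seed_id: str, gene_id: str
) -> SharedTargetResult:
    """Test whether ``gene_id`` shares unexpectedly many miRNAs with the seed.

    Returns P(X >= k) for the overlap k under random target-set draws from
    the universe.  A gene absent from the index is a null observation:
    k = 0, n = 0, p = 1, flagged via ``indexed=False``.
    """
    seed = _seed_set(index, seed_id)
    N, K = len(index.universe), len(seed)
    if gene_id not in index:
        return SharedTargetResult(gene_id, 0, K, 0, N, 1.0, (), indexed=False)
    gset = index.target_set(gene_id)
    shared = seed & gset
    k, n = len(shared), len(gset)
    p = hypergeom_upper_tail(HypergeomParams(N=N, K=K, n=n, k=k))
    return SharedTargetResult(gene_id, k, K, n, N, p, tuple(sorted(shared)))


def bridging_mirnas(index: TargetSetIndex, seed_id: str, gene_id: str) -> list[str]:
    """miRNAs interacting with both the seed and the gene, deterministically ordered.

    Ordered by descending mean interaction score over the two pair edges
    when scores are present, ties (and the no-score case) broken
    lexicographically.  Unindexed identifiers yield an empty list with a
    warning.
    """
    if seed_id not in index or gene_id not in index:
        warnings.warn(
            f"identifier not indexed: {seed_id if seed_id not in index else gene_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    shared = index.target_set(seed_id) & index.target_set(gene_id)

    def key(m: str):
        vals = [
            index.pair_scores[pair]
            for pair in ((seed_id, m), (gene_id, m))
            if pair in index.pair_scores
        ]
        mean_score = float(np.mean(vals)) if vals else float("-inf")
        return (-mean_score, m)

    return sorted(shared, key=key)


class SharedTargetEnrichment:
    """Shared-target screen of many genes against one seed lncRNA.

    Parameters
    ----------
    index : TargetSetIndex
    seed_id : str
        Must be indexed with a non-empty target set.
    gene_ids : iterable of str
        Genes to test; unindexed genes receive k = 0, p = 1.
    alpha : float
        Significance gate, applied to the raw p by default.
    adjust : bool
        Gate on BH-adjusted q instead of raw p.
    """

    def __init__(self, index, seed_id, gene_ids, alpha: float = 0.05, adjust: bool = False):
        _seed_set(index, seed_id)  # validate eagerly
        if not 0.0 <= alpha <= 1.0:
            raise InvalidInputError("alpha must be in [0, 1]")
        self.index = index
        self.seed_id = seed_id
        self.gene_ids = list(gene_ids)
        self.alpha = float(alpha)
        self.adjust = adjust

    def fit(self) -> "EnrichmentResults":
        results = [shared_mirna_test(self.index, self.seed_id, g) for g in self.gene_ids]
        p = np.array([r.p for r in results])
        q = benjamini_hochberg(p) if len(p) else np.array([])
        gate = q if self.adjust else p
        passes = gate < self.alpha
        table = pd.DataFrame(
            {
                "k": [r.k for r in results],
                "K": [r.K for r in results],
                "n": [r.n for r in results],
                "N": [r.N for r in results],
                "p": p,
                "q": q,
                "passes": passes,
                "indexed": [r.indexed for r in results],
            },
            index=pd.Index(self.gene_ids, name="gene"),
        )
        return EnrichmentResults(model=self, table=table, results=results)


@dataclass
class EnrichmentResults:
    """Per-gene shared-target statistics with pass flags."""

    model: SharedTargetEnrichment
    table: pd.DataFrame
    results: list = field(default_factory=list)

    def genes(self) -> set[str]:
        """Genes passing the shared-target gate."""
        return set(self.table.index[self.table["passes"]])

    def bridging(self, gene_id: str) -> list[str]:
        return bridging_mirnas(self.model.index, self.model.seed_id, gene_id)

    def summary(self) -> str:
        m = self.model
        gate = "BH q" if m.adjust else "raw p"
        K = len(m.index.target_set(m.seed_id))
        return "\n".join(
            [
                "Shared miRNA-target enrichment",
                f"  seed: {m.seed_id}  K = {K}  universe N = {len(m.index.universe)}",
                f"  gate: {gate} < {m.alpha}",
                f"  genes tested: {len(self.table)}  passing: {len(self.genes())}",
            ]
        )


def cerna_screen_all(
    index: TargetSetIndex,
    seed_id: str,
    gene_ids,
    alpha: float = 0.05,
    adjust: bool = False,
) -> EnrichmentResults:
    """Convenience wrapper: build and fit a :class:`SharedTargetEnrichment`."""
    return SharedTargetEnrichment(index, seed_id, gene_ids, alpha, adjust).fit()
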