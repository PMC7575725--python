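"""End-to-end evidence-intersection screen for ceRNA candidates.

Four independent evidence streams are computed and intersected:

1. differential expression between case and control groups,
2. co-expression with the seed lncRNA across all samples,
3. shared miRNA-target enrichment against the seed (hypergeometric),
4. tissue-specific annotation by keyword.

A candidate gene must pass all four gates.  The seed lncRNA's own DE
status is reported separately and the seed is never listed as a candidate.
Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from .annotation import read_annotation_table, tissue_gene_set
from .coexpression import SeedCorrelation, CorrelationResults
from .diffexpr import DifferentialExpression, DEResults, PRESETS
from .enrichment import (
    SharedTargetEnrichment,
    EnrichmentResults,
    TargetSetIndex,
    bridging_mirnas,
    read_interaction_table,
)
from .errors import InvalidConfigError
from .io import read_design, read_expression_table

logger = logging.getLogger("cernascreen")

__all__ = [
    "ScreenConfig",
    "CeRNAScreen",
    "ScreenResults",
    "run_screen",
    "report_venn_counts",
]


@dataclass
class ScreenConfig:
    """File paths and thresholds of a full screen run.

    Mirrors a flat YAML document; CLI flags override individual keys.
    """

    matrix: str = ""
    design: str = ""
    interactions: str = ""
    annotations: str = ""
    seed_id: str = ""
    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    de_preset: str | None = None
    r_threshold: float = 0.5
    cerna_alpha: float = 0.05
    cerna_adjust: bool = False
    tissue_keyword: str = "lung"
    random_seed: int = 0

    def __post_init__(self):
        if not self.fc_threshold > 0:
            raise InvalidConfigError("fc_threshold must be positive")
        for name in ("de_alpha", "cerna_alpha"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must be in (0, 1]")
        if not -1.0 <= self.r_threshold < 1.0:
            raise InvalidConfigError("r_threshold must be in [-1, 1)")
        if self.de_preset is not None and self.de_preset not in PRESETS:
            raise InvalidConfigError(f"unknown DE preset {self.de_preset!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ScreenConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class CeRNAScreen:
    """In-memory screen over already-parsed inputs.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Gene x sample log2 expression.
    design : pandas.Series
        sample -> {"case", "control"}.
    interactions : pandas.DataFrame or TargetSetIndex
        RNA-RNA interaction table (or a pre-built index).
    annotations : pandas.DataFrame
        gene/term_name annotation table.
    seed_id : str
        The seed lncRNA, present in the matrix and the interaction index.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design: pd.Series,
        interactions,
        annotations: pd.DataFrame,
        seed_id: str,
        config: ScreenConfig | None = None,
    ):
        self.config = config or ScreenConfig(seed_id=seed_id)
        self.matrix = matrix
        self.design = design
        self.index = (
            interactions
            if isinstance(interactions, TargetSetIndex)
            else TargetSetIndex.from_table(interactions)
        )
        self.annotations = annotations
        self.seed_id = seed_id

    def fit(self) -> "ScreenResults":
        cfg = self.config
        logger.info("stage=de screening %d genes", len(self.matrix))
        if cfg.de_preset:
            de_model = DifferentialExpression.from_preset(
                self.matrix, self.design, preset=cfg.de_preset
            )
        else:
            de_model = DifferentialExpression(
                self.matrix, self.design, cfg.fc_threshold, cfg.de_alpha
            )
        de = de_model.fit()

        logger.info("stage=corr seed=%s", self.seed_id)
        corr = SeedCorrelation(self.matrix, self.seed_id, cfg.r_threshold).fit()

        genes = [g for g in self.matrix.index if g != self.seed_id]
        logger.info("stage=cerna universe=%d", len(self.index.universe))
        cerna = SharedTargetEnrichment(
            self.index, self.seed_id, genes, cfg.cerna_alpha, cfg.cerna_adjust
        ).fit()

        logger.info("stage=tissue keyword=%r", cfg.tissue_keyword)
        tissue = tissue_gene_set(self.annotations, cfg.tissue_keyword)

        de_set = de.genes() - {self.seed_id}
        gate_sets = {
            "de": de_set,
            "correlation": corr.genes(),
            "shared_target": cerna.genes(),
            "tissue": tissue & set(self.matrix.index),
        }
        candidates = sorted(set.intersection(*gate_sets.values()))
        logger.info(
            "gates de=%d corr=%d cerna=%d tissue=%d -> candidates=%d",
            *(len(gate_sets[k]) for k in ("de", "correlation", "shared_target", "tissue")),
            len(candidates),
        )
        if not candidates:
            logger.warning("empty candidate set: no gene passed all four gates")

        rows = []
        for g in candidates:
            ct = cerna.table.loc[g]
            rows.append(
                {
                    "gene": g,
                    "de_status": de.table.loc[g, "status"],
                    "log2_fc": de.table.loc[g, "log2_fc"],
                    "fold_change": de.table.loc[g, "fold_change"],
                    "de_q": de.table.loc[g, "q"],
                    "r": corr.table.loc[g, "r"],
                    "corr_p": corr.table.loc[g, "p"],
                    "k": int(ct["k"]),
                    "K": int(ct["K"]),
                    "n": int(ct["n"]),
                    "N": int(ct["N"]),
                    "cerna_p": ct["p"],
                    "tissue": True,
                    "bridging_mirnas": ",".join(
                        bridging_mirnas(self.index, self.seed_id, g)
                    ),
                }
            )
        cand_table = pd.DataFrame(
            rows,
            columns=[
                "gene", "de_status", "log2_fc", "fold_change", "de_q", "r",
                "corr_p", "k", "K", "n", "N", "cerna_p", "tissue",
                "bridging_mirnas",
            ],
        ).set_index("gene")

        seed_de = (
            de.table.loc[self.seed_id]
            if self.seed_id in de.table.index
            else None
        )
        return ScreenResults(
            model=self,
            candidates=cand_table,
            gate_sets=gate_sets,
            de=de,
            correlation=corr,
            enrichment=cerna,
            tissue_genes=tissue,
            seed_de=seed_de,
            venn=report_venn_counts(gate_sets),
        )


@dataclass
class ScreenResults:
    """Candidate table plus per-gate evidence and Venn bookkeeping."""

    model: CeRNAScreen
    candidates: pd.DataFrame
    gate_sets: dict
    de: DEResults
    correlation: CorrelationResults
    enrichment: EnrichmentResults
    tissue_genes: set
    seed_de: pd.Series | None
    venn: pd.DataFrame

    def summary(self) -> str:
        g = self.gate_sets
        lines = [
            "ceRNA evidence-intersection screen",
            f"  seed lncRNA: {self.model.seed_id}",
        ]
        if self.seed_de is not None:
            lines.append(
                f"  seed DE: status={self.seed_de['status']}"
                f" log2FC={self.seed_de['log2_fc']:.3f} q={self.seed_de['q']:.3g}"
            )
        lines += [
            f"  gate sizes: DE={len(g['de'])}  corr={len(g['correlation'])}"
            f"  shared-target={len(g['shared_target'])}  tissue={len(g['tissue'])}",
            f"  candidates (all four gates): {len(self.candidates)}",
        ]
        for gene, row in self.candidates.iterrows():
            lines.append(
                f"    {gene}: {row['de_status']}, r={row['r']:.3f},"
                f" k/K={row['k']}/{row['K']}, p={row['cerna_p']:.3g},"
                f" miRNAs=[{row['bridging_mirnas']}]"
            )
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Write all stage tables, the Venn counts and the effective config."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", float_format="%.10g")
        self.candidates.to_csv(out / "candidates.tsv", **fmt)
        self.venn.to_csv(out / "venn_counts.tsv", index=False, **fmt)
        self.de.table.to_csv(out / "de.tsv", **fmt)
        self.correlation.table.to_csv(out / "corr.tsv", **fmt)
        self.enrichment.table.to_csv(out / "cerna.tsv", **fmt)
        with open(out / "tissue_genes.txt", "w") as fh:
            for g in sorted(self.tissue_genes):
                fh.write(g + "\n")
        self.model.config.to_yaml(out / "effective_config.yaml")


def report_venn_counts(gate_sets: dict[str, set]) -> pd.DataFrame:
    """Sizes of every gate set and of all their intersections.

    One row per non-empty combination of gate names (singletons through
    the full intersection), ordered by combination size then name; the
    counts are what a Venn diagram of the evidence streams displays.
    """
    names = sorted(gate_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(gate_sets[c] for c in combo))
            rows.append({"sets": "&".join(combo), "n_sets": r, "count": len(inter)})
    return pd.DataFrame(rows, columns=["sets", "n_sets", "count"])


def run_screen(config: ScreenConfig) -> ScreenResults:
    """Load all files named in ``config``, run the screen, return results."""
    for name in ("matrix", "design", "interactions", "annotations"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise InvalidConfigError(f"config.{name} missing or not found: {path!r}")
    if not config.seed_id:
        raise InvalidConfigError("config.seed_id is required")
    matrix = read_expression_table(config.matrix)
    design = read_design(config.design)
    interactions = read_interaction_table(config.interactions)
    annotations = read_annotation_table(config.annotations)
    screen = CeRNAScreen(matrix, design, interactions, annotations, config.seed_id, config)
    return screen.fit()
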