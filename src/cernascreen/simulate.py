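"""Synthetic inputs with planted ground truth for every screening stage.

The generators emulate the statistical structure the ceRNA screen assumes:

* a two-group (8 + 8 samples) log2 expression matrix with planted
  fold-change effects and a single shared latent factor that creates a
  co-expression block around the seed lncRNA
  (``x_gj = mu_g + beta_g * 1[case] + lambda_g * f_j + eps_gj``,
  ``f_j ~ N(0,1)``, ``eps ~ N(0, sigma^2)``);
* an RNA-RNA interaction table in which planted ceRNA genes share a fixed
  fraction of the seed's miRNA targets while background RNAs draw target
  sets uniformly at random;
* a gene-to-GO-term-name annotation table with a tissue keyword planted on
  the true candidates (plus configurable decoys);
* qPCR Ct replicate tables with a planted fold change.

Every generator is a pure function of ``(config, random_seed)``; stage
seeds are derived deterministically from the single global seed, so
identical configs produce bit-identical files.  Each simulation emits a
:class:`SynthTruth` record for recovery testing.

The *default scenario* (:func:`default_scenario`) adds per-gate distractor
families: for each of the four evidence gates, five genes engineered to
pass the other three gates and fail exactly that one.  Recovering the
planted triplet genes and nothing else therefore exercises every gate's
discriminative effect individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "ScenarioData",
    "simulate_expression",
    "simulate_interactions",
    "simulate_annotations",
    "simulate_ct_table",
    "simulate_probe_matrix",
    "default_scenario",
    "write_scenario",
]

LUNG_TERMS = (
    "lung development",
    "lung alveolus development",
    "lung epithelium development",
)
OTHER_TERMS = (
    "heart development",
    "kidney development",
    "immune response",
    "cell cycle",
    "apoptotic process",
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the array study the screen is designed for: 8 case and
    8 control samples, ~2,000 genes on the log2 scale, a seed lncRNA that
    is itself differentially expressed and loads the latent co-expression
    factor, a universe of 500 miRNAs of which the seed targets 30, planted
    ceRNA genes sharing 80% of those targets, and triplicate qPCR with a
    fourfold planted effect.
    """

    n_case: int = 8
    n_control: int = 8
    n_genes: int = 2000
    n_planted_de: int = 50
    beta: float = 2.0          # planted log2 fold change
    n_correlated: int = 50
    lam: float = 0.5           # latent-factor loading of planted correlated genes
    seed_lam: float = 0.75     # latent-factor loading of the seed lncRNA
    de_distractor_beta: float = 1.0   # sub-significant effect of the DE-gate distractors
    de_distractor_lam: float = 1.0    # their loading (matched so the t-test stays quiet)
    sigma: float = 0.25        # residual noise sd (log2 units)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    n_mirnas: int = 500
    seed_targets: int = 30     # K, the seed lncRNA's target count
    n_cerna: int = 3
    shared_fraction: float = 0.8
    n_background_targets: int = 30
    n_background_rnas: int = 200
    n_distractors_per_gate: int = 5
    n_decoy_eligible: int = 100
    decoy_tissue_fraction: float = 0.5
    tissue_keyword: str = "lung"
    qpcr_fold: float = 4.0
    ct_noise_sd: float = 0.2
    qpcr_samples: int = 3
    qpcr_replicates: int = 3
    seed_id: str = "Malat1"
    random_seed: int = 42

    def __post_init__(self):
        positive = [
            "n_case", "n_control", "n_genes", "n_mirnas", "seed_targets",
            "n_cerna", "qpcr_samples", "qpcr_replicates",
        ]
        for name in positive:
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_planted_de < 0 or self.n_correlated < 0:
            raise InvalidConfigError("planted counts must be >= 0")
        if self.n_planted_de + self.n_correlated + 1 > self.n_genes:
            raise InvalidConfigError("planted subsets exceed n_genes")
        if not 0.0 < self.shared_fraction <= 1.0:
            raise InvalidConfigError("shared_fraction must be in (0, 1]")
        if min(self.sigma, self.lam, self.seed_lam, self.ct_noise_sd) < 0:
            raise InvalidConfigError("sigma, lam, seed_lam, ct_noise_sd must be >= 0")
        if self.seed_targets > self.n_mirnas or self.n_background_targets > self.n_mirnas:
            raise InvalidConfigError("target counts cannot exceed the miRNA universe")
        if not 0.0 <= self.decoy_tissue_fraction <= 1.0:
            raise InvalidConfigError("decoy_tissue_fraction must be in [0, 1]")
        if self.qpcr_fold <= 0:
            raise InvalidConfigError("qpcr_fold must be > 0")
        if not 0 <= self.random_seed < 2**31:
            raise InvalidConfigError("random_seed must be in [0, 2^31)")


@dataclass
class SynthTruth:
    """Planted parameters emitted alongside every simulation."""

    seed_id: str = ""
    planted_de: dict = field(default_factory=dict)       # gene -> log2 effect
    planted_correlated: list = field(default_factory=list)
    planted_cerna: list = field(default_factory=list)
    bridging: dict = field(default_factory=dict)         # gene -> shared miRNAs
    distractors: dict = field(default_factory=dict)      # failed-gate -> genes
    tissue_genes: list = field(default_factory=list)
    qpcr_fold: float = float("nan")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SynthTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    # stage-level generators derived deterministically from the global seed
    return np.random.default_rng([config.random_seed, stage])


def _sample_ids(config: SynthConfig) -> tuple[list[str], list[str]]:
    case = [f"case_{i+1}" for i in range(config.n_case)]
    ctrl = [f"ctrl_{i+1}" for i in range(config.n_control)]
    return case, ctrl


def _expression_from_effects(
    gene_ids: list[str],
    beta: np.ndarray,
    lam: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    case, ctrl = _sample_ids(config)
    samples = case + ctrl
    n_s = len(samples)
    g = len(gene_ids)
    mu = config.baseline_mean + config.baseline_sd * rng.standard_normal(g)
    f = rng.standard_normal(n_s)  # shared latent factor
    eps = config.sigma * rng.standard_normal((g, n_s))
    is_case = np.array([1.0] * len(case) + [0.0] * len(ctrl))
    values = mu[:, None] + beta[:, None] * is_case[None, :] + lam[:, None] * f[None, :] + eps
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    design = pd.Series(
        ["case"] * len(case) + ["control"] * len(ctrl), index=samples, name="group"
    )
    return matrix, design


def simulate_expression(config: SynthConfig) -> tuple[pd.DataFrame, pd.Series, SynthTruth]:
    """Two-group expression matrix with planted DE and co-expression structure.

    The seed lncRNA (row ``config.seed_id``) carries both the planted log2
    effect and the latent-factor loading; ``n_planted_de`` genes carry the
    effect only and a disjoint set of ``n_correlated`` genes the loading
    only.  All remaining genes are pure noise around their baselines.
    """
    n = config.n_genes
    gene_ids = [config.seed_id] + [f"gene{i:05d}" for i in range(1, n)]
    beta = np.zeros(n)
    lam = np.zeros(n)
    beta[0] = config.beta
    lam[0] = config.seed_lam
    de_idx = np.arange(1, 1 + config.n_planted_de)
    corr_idx = np.arange(1 + config.n_planted_de, 1 + config.n_planted_de + config.n_correlated)
    beta[de_idx] = config.beta
    lam[corr_idx] = config.lam
    matrix, design = _expression_from_effects(gene_ids, beta, lam, config, _rng(config, 1))
    planted_de = {gene_ids[i]: float(config.beta) for i in de_idx}
    planted_de[config.seed_id] = float(config.beta)  # the seed carries the effect too
    truth = SynthTruth(
        seed_id=config.seed_id,
        planted_de=planted_de,
        planted_correlated=[gene_ids[i] for i in corr_idx],
    )
    return matrix, design, truth


def _interaction_rows(
    target_sets: dict[str, tuple[str, set[str]]],
    mirnas: list[str],
    rng: np.random.Generator,
    with_scores: bool = True,
) -> pd.DataFrame:
    """Materialise target sets as unordered interaction rows.

    ``target_sets`` maps rna id -> (category, set of miRNA ids).  Any
    universe miRNA absent from every set is padded in with a
    miRNA-miRNA row so the realised universe equals ``mirnas`` exactly.
    """
    rows = []
    seen: set[str] = set()
    for rna in sorted(target_sets):
        cat, targets = target_sets[rna]
        for m in sorted(targets):
            seen.add(m)
            score = round(float(rng.uniform(0, 1)), 3) if with_scores else np.nan
            if rng.random() < 0.5:  # either column order, exercised on purpose
                rows.append((rna, cat, m, "miRNA", score))
            else:
                rows.append((m, "miRNA", rna, cat, score))
    anchor = mirnas[0]
    for m in mirnas:
        if m not in seen and m != anchor:
            rows.append((m, "miRNA", anchor, "miRNA", np.nan))
    if anchor not in seen:
        rows.append((anchor, "miRNA", anchor, "miRNA", np.nan))
    return pd.DataFrame(
        rows, columns=["rna1", "rna1_category", "rna2", "rna2_category", "score"]
    )


def simulate_interactions(
    config: SynthConfig,
    cerna_ids: list[str] | None = None,
    background_ids: list[str] | None = None,
    nonshared_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Interaction table with planted shared-target structure.

    The seed lncRNA receives exactly ``seed_targets`` (K) miRNAs.  Planted
    ceRNA genes share ``ceil(shared_fraction * K)`` of them, topped up with
    non-seed miRNAs to ``n_background_targets`` total.  Background RNAs
    draw their targets uniformly from the whole universe;
    ``nonshared_ids`` (used for distractor genes) draw only from the
    non-seed portion, guaranteeing zero overlap.
    """
    rng = _rng(config, 2)
    mirnas = [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    if cerna_ids is None:
        cerna_ids = [f"cerna{i+1}" for i in range(config.n_cerna)]
    if background_ids is None:
        background_ids = [f"bg{i+1:04d}" for i in range(config.n_background_rnas)]
    nonshared_ids = nonshared_ids or []

    seed_set = {str(m) for m in rng.choice(mirnas, size=config.seed_targets, replace=False)}
    non_seed = sorted(set(mirnas) - seed_set)
    n_shared = math.ceil(config.shared_fraction * config.seed_targets)
    n_extra = max(0, config.n_background_targets - n_shared)

    target_sets: dict[str, tuple[str, set[str]]] = {
        config.seed_id: ("lncRNA", seed_set)
    }
    truth = SynthTruth(seed_id=config.seed_id, planted_cerna=list(cerna_ids))
    for g in cerna_ids:
        shared = {str(m) for m in rng.choice(sorted(seed_set), size=n_shared, replace=False)}
        extra = {str(m) for m in rng.choice(non_seed, size=n_extra, replace=False)}
        target_sets[g] = ("mRNA", shared | extra)
        truth.bridging[g] = sorted(shared)
    for g in nonshared_ids:
        target_sets[g] = (
            "mRNA",
            {str(m) for m in rng.choice(non_seed, size=config.n_background_targets, replace=False)},
        )
    for g in background_ids:
        target_sets[g] = (
            "mRNA",
            {str(m) for m in rng.choice(mirnas, size=config.n_background_targets, replace=False)},
        )
    table = _interaction_rows(target_sets, mirnas, rng)
    return table, truth


def simulate_annotations(
    config: SynthConfig,
    planted_ids: list[str] | None = None,
    unannotated_ids: list[str] | None = None,
    decoy_eligible_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Gene-to-term annotation table with the tissue keyword planted.

    All ``planted_ids`` (default: the ceRNA gene names) receive a
    keyword-matching term; ``unannotated_ids`` receive only non-matching
    terms; each decoy-eligible gene receives a matching term with
    probability ``decoy_tissue_fraction``.
    """
    rng = _rng(config, 3)
    if planted_ids is None:
        planted_ids = [f"cerna{i+1}" for i in range(config.n_cerna)]
    if decoy_eligible_ids is None:
        decoy_eligible_ids = [f"bg{i+1:04d}" for i in range(config.n_decoy_eligible)]
    unannotated_ids = unannotated_ids or []

    rows = []
    tissue_genes = []
    for g in planted_ids:
        rows.append((g, LUNG_TERMS[int(rng.integers(len(LUNG_TERMS)))]))
        tissue_genes.append(g)
    for g in unannotated_ids:
        rows.append((g, OTHER_TERMS[int(rng.integers(len(OTHER_TERMS)))]))
    for g in decoy_eligible_ids:
        if rng.random() < config.decoy_tissue_fraction:
            rows.append((g, LUNG_TERMS[int(rng.integers(len(LUNG_TERMS)))]))
            tissue_genes.append(g)
        else:
            rows.append((g, OTHER_TERMS[int(rng.integers(len(OTHER_TERMS)))]))
    table = pd.DataFrame(rows, columns=["gene", "term_name"]).drop_duplicates(
        ignore_index=True
    )
    truth = SynthTruth(seed_id=config.seed_id, tissue_genes=tissue_genes)
    return table, truth


def simulate_ct_table(
    config: SynthConfig, target: str | None = None, reference: str = "GAPDH"
) -> tuple[pd.DataFrame, SynthTruth]:
    """Replicated Ct table with a planted fold change on the target assay.

    Treated-group target Cts sit ``log2(fold)`` cycles below the control
    group's; the reference assay is common to both groups.  Replicate
    noise is Gaussian on the Ct scale.
    """
    rng = _rng(config, 4)
    target = target or config.seed_id
    base_ref, base_target = 20.0, 25.0
    shift = math.log2(config.qpcr_fold)
    rows = []
    for group, prefix in (("treated", "t"), ("control", "c")):
        for s in range(1, config.qpcr_samples + 1):
            sample = f"{prefix}{s}"
            for rep in range(1, config.qpcr_replicates + 1):
                noise = config.ct_noise_sd * rng.standard_normal(2)
                t_ct = base_target - (shift if group == "treated" else 0.0) + noise[0]
                r_ct = base_ref + noise[1]
                rows.append((sample, group, target, rep, float(t_ct)))
                rows.append((sample, group, reference, rep, float(r_ct)))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "assay", "replicate", "ct"])
    truth = SynthTruth(seed_id=config.seed_id, qpcr_fold=float(config.qpcr_fold))
    return table, truth


def simulate_probe_matrix(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, SynthTruth]:
    """Probe-level emission of the expression simulation, for collapse testing.

    The first 20 genes are split into two probes whose values straddle the
    gene value symmetrically (so the probe mean reproduces it exactly);
    five multi-symbol probes and five unannotated probes are appended.
    Returns (probe_matrix, probe_annotation, gene_matrix, design, truth).
    """
    matrix, design, truth = simulate_expression(config)
    rng = _rng(config, 5)
    probe_rows, ann_rows = [], []
    n_split = min(20, len(matrix))
    for i, (gene, row) in enumerate(matrix.iterrows()):
        desc = (
            f"long non-coding RNA {gene}" if gene == config.seed_id else f"{gene} transcript"
        )
        if i < n_split:
            delta = 0.1 + 0.2 * rng.random()
            probe_rows.append((f"{gene}_p1", row + delta))
            probe_rows.append((f"{gene}_p2", row - delta))
            ann_rows.append((f"{gene}_p1", gene, desc))
            ann_rows.append((f"{gene}_p2", gene, desc))
        else:
            probe_rows.append((f"{gene}_p1", row))
            ann_rows.append((f"{gene}_p1", gene, desc))
    for j in range(5):
        vals = pd.Series(rng.normal(8, 1, matrix.shape[1]), index=matrix.columns)
        probe_rows.append((f"multi_p{j}", vals))
        ann_rows.append((f"multi_p{j}", f"GeneX{j} /// GeneY{j}", "ambiguous probe"))
    for j in range(5):
        vals = pd.Series(rng.normal(8, 1, matrix.shape[1]), index=matrix.columns)
        probe_rows.append((f"anon_p{j}", vals))
        ann_rows.append((f"anon_p{j}", "", ""))
    probe_matrix = pd.DataFrame(
        {pid: vals for pid, vals in probe_rows}
    ).T
    probe_matrix.index.name = "probe"
    annotation = pd.DataFrame(
        ann_rows, columns=["probe_id", "gene_symbol", "description"]
    ).set_index("probe_id")
    return probe_matrix, annotation, matrix, design, truth


@dataclass
class ScenarioData:
    """All inputs of the default end-to-end scenario, plus ground truth."""

    matrix: pd.DataFrame
    design: pd.Series
    interactions: pd.DataFrame
    annotations: pd.DataFrame
    ct: pd.DataFrame
    truth: SynthTruth
    config: SynthConfig


def default_scenario(config: SynthConfig | None = None) -> ScenarioData:
    """The reference end-to-end scenario with per-gate distractor families.

    Planted genes (defaults in parentheses):

    * ``cerna1..3`` — true ceRNA triplet genes: upregulated, loaded on the
      latent factor, sharing 80% of the seed's miRNA targets, annotated to
      a lung term.  These must be the screen's only candidates.
    * ``noDE1..5`` — pass correlation, shared-target and tissue gates but
      fail differential expression: their group effect
      (``de_distractor_beta``, default 1.0) is paired with an equal factor
      loading, so the within-group variance keeps the t-test far from BH
      significance while the pooled correlation with the seed stays high.
    * ``noCorr1..5`` — *down*regulated with no factor loading, so they
      pass the DE gate while correlating negatively with the seed.
    * ``noShare1..5`` — pass DE/correlation/tissue but draw their miRNA
      targets exclusively outside the seed's set (overlap 0 by design, so
      the failure is a property of the gate, not of sampling luck).
    * ``noLung1..5`` — pass DE/correlation/shared-target but are annotated
      only to non-lung terms.

    Remaining genes are background noise; a slice of them receives random
    target sets and decoy tissue annotations.
    """
    config = config or SynthConfig()
    m = config.n_distractors_per_gate
    cerna = [f"cerna{i+1}" for i in range(config.n_cerna)]
    no_de = [f"noDE{i+1}" for i in range(m)]
    no_corr = [f"noCorr{i+1}" for i in range(m)]
    no_share = [f"noShare{i+1}" for i in range(m)]
    no_lung = [f"noLung{i+1}" for i in range(m)]
    special = [config.seed_id] + cerna + no_de + no_corr + no_share + no_lung
    n_bg = config.n_genes - len(special)
    if n_bg < config.n_background_rnas:
        raise InvalidConfigError("n_genes too small for the scenario's families")
    background = [f"gene{i:05d}" for i in range(1, n_bg + 1)]
    gene_ids = special + background

    beta = np.zeros(len(gene_ids))
    lam = np.zeros(len(gene_ids))
    effects = {config.seed_id: (config.beta, config.seed_lam)}
    for g in cerna + no_share + no_lung:
        effects[g] = (config.beta, config.lam)
    for g in no_de:
        effects[g] = (config.de_distractor_beta, config.de_distractor_lam)
    for g in no_corr:
        effects[g] = (-config.beta, 0.0)
    for i, g in enumerate(gene_ids):
        if g in effects:
            beta[i], lam[i] = effects[g]
    matrix, design = _expression_from_effects(gene_ids, beta, lam, config, _rng(config, 1))

    interactions, itruth = simulate_interactions(
        config,
        cerna_ids=cerna + no_de + no_corr + no_lung,
        background_ids=background[: config.n_background_rnas],
        nonshared_ids=no_share,
    )
    annotations, atruth = simulate_annotations(
        config,
        planted_ids=cerna + no_de + no_corr + no_share,
        unannotated_ids=no_lung,
        decoy_eligible_ids=background[: config.n_decoy_eligible],
    )
    ct, qtruth = simulate_ct_table(config)

    truth = SynthTruth(
        seed_id=config.seed_id,
        # genes planted to clear the DE gate (the noDE family's sub-threshold
        # effect is deliberately not one of them)
        planted_de={
            g: float(effects[g][0])
            for g in effects
            if abs(effects[g][0]) >= config.beta
        },
        planted_correlated=[g for g in effects if effects[g][1] != 0.0 and g != config.seed_id],
        planted_cerna=cerna,
        bridging={g: itruth.bridging[g] for g in cerna},
        distractors={
            "de": no_de,
            "correlation": no_corr,
            "shared_target": no_share,
            "tissue": no_lung,
        },
        tissue_genes=atruth.tissue_genes,
        qpcr_fold=float(config.qpcr_fold),
    )
    return ScenarioData(matrix, design, interactions, annotations, ct, truth, config)


def write_scenario(scenario: ScenarioData, outdir) -> dict[str, str]:
    """Write every scenario file (TSV + truth.yaml) into ``outdir``."""
    from pathlib import Path
    from .io import write_expression_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "design": out / "design.tsv",
        "interactions": out / "interactions.tsv",
        "annotations": out / "annotations.tsv",
        "ct": out / "ct.tsv",
        "truth": out / "truth.yaml",
    }
    write_expression_table(scenario.matrix, paths["matrix"], id_label="gene")
    scenario.design.rename_axis("sample_id").reset_index().to_csv(
        paths["design"], sep="\t", index=False
    )
    scenario.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    scenario.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    scenario.ct.to_csv(paths["ct"], sep="\t", index=False)
    scenario.truth.to_yaml(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
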