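"""Differential-expression screen between case and control groups.

A gene is called *up* when its linear fold change (case over control,
``2**log2FC``) exceeds the threshold and its BH-adjusted p-value is below
alpha; *down* symmetrically for fold change below the reciprocal; *ns*
otherwise.  The per-gene test is a pooled two-sided Student t on log2
values (Welch available), with BH adjustment computed across all tested
genes.

Two documented gate presets exist because published screens state them
both ways: the default ``methods`` preset (linear |FC| > 1.5, BH q < 0.05)
and a ``volcano`` preset (|log2 FC| > 1.5, raw p < 0.01) matching the
looser convention often used to draw volcano plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidDesignError, InvalidInputError
from .io import validate_design
from .stats import benjamini_hochberg

__all__ = ["DifferentialExpression", "DEResults", "de_screen", "PRESETS"]

PRESETS: dict[str, dict] = {
    "methods": dict(fc_threshold=1.5, alpha=0.05, use_adjusted=True, fc_on_log_scale=False),
    "volcano": dict(fc_threshold=1.5, alpha=0.01, use_adjusted=False, fc_on_log_scale=True),
}


class DifferentialExpression:
    """Two-group differential expression model on a log2 expression matrix.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x samples, log2 scale.
    design : pandas.Series
        sample id -> group label in {"case", "control"}; every matrix
        column must be labelled and each group needs >= 2 samples.
    fc_threshold : float
        Fold-change gate.  Interpreted on the linear scale by default
        (ratio > 1.5 or < 1/1.5); see ``fc_on_log_scale``.
    alpha : float
        Significance gate on the BH-adjusted p (or raw p, see
        ``use_adjusted``).
    variant : {"pooled", "welch"}
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design: pd.Series,
        fc_threshold: float = 1.5,
        alpha: float = 0.05,
        variant: str = "pooled",
        use_adjusted: bool = True,
        fc_on_log_scale: bool = False,
    ):
        validate_design(design)
        unlabelled = [s for s in matrix.columns if s not in design.index]
        if unlabelled:
            raise InvalidDesignError(f"samples without a group label: {unlabelled}")
        if not fc_threshold > (0.0 if fc_on_log_scale else 1.0):
            raise InvalidInputError("fc_threshold must exceed 1 (linear) or 0 (log2)")
        if not 0.0 < alpha < 1.0:
            raise InvalidInputError("alpha must be in (0, 1)")
        if variant not in ("pooled", "welch"):
            raise InvalidInputError(f"unknown t-test variant {variant!r}")
        design = design.loc[matrix.columns]
        self.case_cols = design.index[design == "case"]
        self.control_cols = design.index[design == "control"]
        if len(self.case_cols) < 2 or len(self.control_cols) < 2:
            raise InvalidDesignError("each group needs at least 2 samples")
        self.matrix = matrix
        self.design = design
        self.fc_threshold = float(fc_threshold)
        self.alpha = float(alpha)
        self.variant = variant
        self.use_adjusted = use_adjusted
        self.fc_on_log_scale = fc_on_log_scale

    @classmethod
    def from_preset(cls, matrix, design, preset: str = "methods", **kw):
        if preset not in PRESETS:
            raise InvalidInputError(f"unknown preset {preset!r}")
        opts = {**PRESETS[preset], **kw}
        return cls(matrix, design, **opts)

    def fit(self) -> "DEResults":
        case = self.matrix[self.case_cols].to_numpy(float)
        ctrl = self.matrix[self.control_cols].to_numpy(float)
        complete = ~(np.isnan(case).any(axis=1) | np.isnan(ctrl).any(axis=1))
        skipped = self.matrix.index[~complete].tolist()
        case, ctrl = case[complete], ctrl[complete]
        genes = self.matrix.index[complete]

        log2_fc = case.mean(axis=1) - ctrl.mean(axis=1)
        with warnings.catch_warnings():
            # constant rows trip scipy's catastrophic-cancellation warning;
            # those genes are handled explicitly below
            warnings.filterwarnings("ignore", "Precision loss occurred", RuntimeWarning)
            res = sps.ttest_ind(case, ctrl, axis=1, equal_var=(self.variant == "pooled"))
        p = np.asarray(res.pvalue, dtype=float)

        # Both groups constant: scipy yields NaN.  Equal means are a vacuous
        # comparison (p = 1, flagged); distinct noise-free means are maximal
        # evidence (p = 0).
        vz = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
        flagged = genes[vz].tolist()
        p[vz & (log2_fc == 0)] = 1.0
        p[vz & (log2_fc != 0)] = 0.0

        q = benjamini_hochberg(p)
        fold_change = np.power(2.0, log2_fc)
        sig = (q if self.use_adjusted else p) < self.alpha
        if self.fc_on_log_scale:
            up_fc = log2_fc > self.fc_threshold
            down_fc = log2_fc < -self.fc_threshold
        else:
            up_fc = fold_change > self.fc_threshold
            down_fc = fold_change < 1.0 / self.fc_threshold
        status = np.where(sig & up_fc, "up", np.where(sig & down_fc, "down", "ns"))

        table = pd.DataFrame(
            {
                "log2_fc": log2_fc,
                "fold_change": fold_change,
                "p": p,
                "q": q,
                "status": status,
            },
            index=genes,
        )
        table.index.name = "gene"
        return DEResults(model=self, table=table, skipped=skipped, flagged=flagged)


@dataclass
class DEResults:
    """Per-gene differential-expression table plus gate bookkeeping."""

    model: DifferentialExpression
    table: pd.DataFrame
    skipped: list = field(default_factory=list)
    flagged: list = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["status"].value_counts()
        return {
            "up": int(c.get("up", 0)),
            "down": int(c.get("down", 0)),
            "ns": int(c.get("ns", 0)),
            "skipped": len(self.skipped),
        }

    def genes(self, status=("up", "down")) -> set[str]:
        """Genes with the given status labels (default: any DE direction)."""
        return set(self.table.index[self.table["status"].isin(status)])

    def summary(self) -> str:
        c = self.counts
        m = self.model
        gate = "BH q" if m.use_adjusted else "raw p"
        scale = "log2" if m.fc_on_log_scale else "linear"
        lines = [
            "Differential expression screen",
            f"  samples: {len(m.case_cols)} case vs {len(m.control_cols)} control",
            f"  test: {m.variant} t, {gate} < {m.alpha}, |FC| > {m.fc_threshold} ({scale})",
            f"  genes tested: {len(self.table)}  skipped (missing values): {c['skipped']}",
            f"  up: {c['up']}  down: {c['down']}  ns: {c['ns']}",
        ]
        return "\n".join(lines)


def de_screen(
    matrix: pd.DataFrame,
    design: pd.Series,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    **kw,
) -> DEResults:
    """Convenience wrapper: build and fit a :class:`DifferentialExpression`."""
    return DifferentialExpression(matrix, design, fc_threshold, alpha, **kw).fit()
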