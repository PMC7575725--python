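"""Relative qPCR quantification by the 2^(-ddCt) (Livak) method.

Technical replicates are averaged on the Ct scale; dCt = Ct(target) -
Ct(reference) per sample; ddCt = mean dCt(treated) - mean dCt(control);
fold = 2^(-ddCt).  The amplification efficiency is fixed at 2 (perfect
doubling), matching the classical formula; no efficiency correction is
applied.  Multiple reference assays (e.g. GAPDH and U6 jointly) are
combined by averaging their Cts, which corresponds to the geometric mean
of the reference expression levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .stats import TestResult, two_sample_t

__all__ = ["read_ct_table", "DeltaDeltaCt", "DdctResults", "ddct_fold_change", "group_compare"]

CT_COLUMNS = ["sample_id", "group", "assay", "replicate", "ct"]
GROUPS = ("treated", "control")


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample_id, group, assay, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "assay": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing Ct columns {sorted(missing)}", line=1)
    validate_ct_table(df)
    return df


def validate_ct_table(table: pd.DataFrame) -> None:
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
        raise InvalidInputError("all Ct values must be finite and > 0")
    bad = set(table["group"].unique()) - set(GROUPS)
    if bad:
        raise InvalidInputError(f"group labels must be treated/control, found {sorted(bad)}")


class DeltaDeltaCt:
    """2^(-ddCt) relative quantification model for one target assay.

    Parameters
    ----------
    table : pandas.DataFrame
        Long-format Ct table (sample_id, group, assay, replicate, ct).
    target : str
        Assay to quantify.
    reference : str or sequence of str
        Reference (housekeeping) assay(s).  With several references their
        Cts are averaged per sample before differencing.
    """

    def __init__(self, table: pd.DataFrame, target: str, reference):
        validate_ct_table(table)
        self.table = table
        self.target = target
        self.references = [reference] if isinstance(reference, str) else list(reference)
        assays = set(table["assay"].unique())
        for a in [target, *self.references]:
            if a not in assays:
                raise InvalidInputError(f"assay {a!r} not present in Ct table")

    def fit(self) -> "DdctResults":
        # replicate averaging on the Ct scale
        mean_ct = (
            self.table.groupby(["sample_id", "group", "assay"], sort=True)["ct"]
            .mean()
            .reset_index()
        )
        wide = mean_ct.pivot(index=["sample_id", "group"], columns="assay", values="ct")

        have_target = wide[self.target].notna()
        have_ref = wide[self.references].notna().all(axis=1)
        dropped = wide.index[have_target & ~have_ref].get_level_values(0).tolist()
        if dropped:
            warnings.warn(
                f"dropping sample(s) without reference Ct: {dropped}",
                RuntimeWarning,
                stacklevel=2,
            )
        keep = have_target & have_ref
        wide = wide[keep]

        ref_ct = wide[self.references].mean(axis=1)
        dct = (wide[self.target] - ref_ct).rename("delta_ct")
        per_sample = dct.reset_index()
        groups = {g: per_sample.loc[per_sample["group"] == g, "delta_ct"] for g in GROUPS}
        for g, v in groups.items():
            if v.empty:
                raise InvalidInputError(f"no usable samples in group {g!r}")

        ddct = float(groups["treated"].mean() - groups["control"].mean())
        fold = float(2.0 ** (-ddct))
        sd = {g: float(v.std(ddof=1)) if len(v) > 1 else float("nan") for g, v in groups.items()}
        return DdctResults(
            model=self,
            fold=fold,
            ddct=ddct,
            delta_ct=per_sample,
            group_sd=sd,
            dropped_samples=dropped,
        )


@dataclass
class DdctResults:
    """Fold-change estimate with the per-sample dCt table behind it."""

    model: DeltaDeltaCt
    fold: float
    ddct: float
    delta_ct: pd.DataFrame
    group_sd: dict
    dropped_samples: list

    def compare_groups(self, variant: str = "pooled") -> TestResult:
        """Two-sample t-test on the per-sample dCt values (treated vs control)."""
        t = self.delta_ct
        return two_sample_t(
            t.loc[t["group"] == "treated", "delta_ct"],
            t.loc[t["group"] == "control", "delta_ct"],
            variant=variant,
        )

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "2^(-ddCt) relative quantification",
                f"  target: {m.target}  reference: {'+'.join(m.references)}",
                f"  ddCt = {self.ddct:.4f}  fold = {self.fold:.4f}",
                f"  dCt SD  treated: {self.group_sd['treated']:.4f}"
                f"  control: {self.group_sd['control']:.4f}",
            ]
        )


def ddct_fold_change(table: pd.DataFrame, target: str, reference) -> DdctResults:
    """Convenience wrapper: build and fit a :class:`DeltaDeltaCt`."""
    return DeltaDeltaCt(table, target, reference).fit()


def group_compare(values_a, values_b, variant: str = "pooled") -> TestResult:
    """Two-group mean comparison (delegates to the pooled/Welch t-test)."""
    return two_sample_t(values_a, values_b, variant=variant)
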