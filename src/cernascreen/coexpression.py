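"""Seed-gene co-expression screen.

Correlates every gene with a chosen seed lncRNA across all samples pooled
(cases and controls together) and gates on the Pearson correlation
coefficient.  The gate is one-sided by default (``r > threshold``) because
a ceRNA is expected to co-vary *positively* with the transcripts whose
miRNAs it sponges; an absolute-value gate is available.  p-values from the
Student-t transform are reported for transparency but not gated on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSeedError, InvalidInputError, MissingSeedError

__all__ = ["SeedCorrelation", "CorrelationResults", "seed_correlation_screen"]


class SeedCorrelation:
    """Correlation of all genes against one seed gene.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x samples, log2 scale; >= 3 samples.
    seed_id : str
        Row identifier of the seed lncRNA; excluded from its own output.
    r_threshold : float
        Pass gate on r (one-sided ``r > r_threshold`` unless
        ``absolute=True``).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        seed_id: str,
        r_threshold: float = 0.5,
        absolute: bool = False,
    ):
        if seed_id not in matrix.index:
            raise MissingSeedError(f"seed {seed_id!r} not in expression matrix")
        if matrix.shape[1] < 3:
            raise InvalidInputError("correlation screen needs >= 3 samples")
        seed = matrix.loc[seed_id].to_numpy(float)
        if np.isnan(seed).any() or np.nanvar(seed) == 0.0:
            raise DegenerateSeedError(f"seed {seed_id!r} is constant or has missing values")
        self.matrix = matrix
        self.seed_id = seed_id
        self.r_threshold = float(r_threshold)
        self.absolute = absolute

    def fit(self) -> "CorrelationResults":
        others = self.matrix.drop(index=self.seed_id)
        values = others.to_numpy(float)
        seed = self.matrix.loc[self.seed_id].to_numpy(float)
        n = len(seed)

        complete = ~np.isnan(values).any(axis=1)
        constant = np.zeros(len(others), dtype=bool)
        constant[complete] = values[complete].var(axis=1) == 0.0
        usable = complete & ~constant
        skipped = others.index[~usable].tolist()
        if skipped:
            warnings.warn(
                f"skipping {len(skipped)} gene(s) with missing values or zero variance",
                RuntimeWarning,
                stacklevel=2,
            )

        sub = values[usable]
        sc = seed - seed.mean()
        gc = sub - sub.mean(axis=1, keepdims=True)
        denom = np.sqrt((gc**2).sum(axis=1) * (sc**2).sum())
        r = np.clip((gc @ sc) / denom, -1.0, 1.0)

        df = n - 2
        with np.errstate(divide="ignore"):
            t = np.abs(r) * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = 2.0 * sps.t.sf(t, df)
        p[np.abs(r) == 1.0] = 0.0

        passes = np.abs(r) > self.r_threshold if self.absolute else r > self.r_threshold
        table = pd.DataFrame(
            {"r": r, "p": p, "passes": passes}, index=others.index[usable]
        )
        table.index.name = "gene"
        return CorrelationResults(model=self, table=table, n_samples=n, skipped=skipped)


@dataclass
class CorrelationResults:
    """Per-gene correlation with the seed, with pass flags."""

    model: SeedCorrelation
    table: pd.DataFrame
    n_samples: int
    skipped: list = field(default_factory=list)

    def genes(self) -> set[str]:
        """Genes passing the correlation gate."""
        return set(self.table.index[self.table["passes"]])

    def summary(self) -> str:
        gate = "|r|" if self.model.absolute else "r"
        return "\n".join(
            [
                "Seed co-expression screen",
                f"  seed: {self.model.seed_id}  samples: {self.n_samples} (pooled)",
                f"  gate: {gate} > {self.model.r_threshold}",
                f"  genes tested: {len(self.table)}  skipped: {len(self.skipped)}",
                f"  passing: {len(self.genes())}",
            ]
        )


def seed_correlation_screen(
    matrix: pd.DataFrame, seed_id: str, r_threshold: float = 0.5, **kw
) -> CorrelationResults:
    """Convenience wrapper: build and fit a :class:`SeedCorrelation`."""
    return SeedCorrelation(matrix, seed_id, r_threshold, **kw).fit()
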