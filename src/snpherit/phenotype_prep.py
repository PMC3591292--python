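"""Covariate adjustment and standardization of raw trait values.

Each trait is regressed on age by ordinary least squares within every
cohort x sex group separately, and the residuals are standardized to
z-scores within the group. Missing trait or covariate values propagate
as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GROUP_COLS = ("cohort", "sex")
COVARIATE_COLS = ("age", "sex", "cohort")


@dataclass
class PhenotypeTable:
    """Sample-indexed table of covariates (age, sex, cohort) and trait columns.

    ``data`` must carry unique sample ids in its index and the covariate
    columns; every other column is treated as a trait unless
    ``trait_names`` narrows the set.
    """

    data: pd.DataFrame
    trait_names: list = field(default=None)

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.index.duplicated().any():
            raise ValueError("sample ids (index) must be unique")
        for col in COVARIATE_COLS:
            if col not in self.data.columns:
                raise ValueError(f"phenotype table lacks covariate column {col!r}")
        if self.trait_names is None:
            self.trait_names = [
                c for c in self.data.columns if c not in COVARIATE_COLS
            ]
        else:
            self.trait_names = list(self.trait_names)
            unknown = set(self.trait_names) - set(self.data.columns)
            if unknown:
                raise ValueError(f"unknown trait columns: {sorted(unknown)}")

    @property
    def samples(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def trait(self, name: str) -> pd.Series:
        if name not in self.trait_names:
            raise KeyError(f"no trait named {name!r}")
        return self.data[name]


def adjust_and_standardize(
    table: PhenotypeTable,
    trait: str,
    group_cols=DEFAULT_GROUP_COLS,
) -> pd.Series:
    """Age-adjusted, group-wise z-scores of one trait.

    Within each group defined by ``group_cols`` (cohort x sex by default)
    the trait is regressed on intercept + age; residuals are divided by
    their (n-1)-denominator standard deviation. A group with zero age
    variance falls back to mean-centering with a warning. Missing trait
    or age values stay missing.

    Returns a series aligned to the table's sample index.
    """
    y = table.trait(trait).astype(float)
    age = table.data["age"].astype(float)
    out = pd.Series(np.nan, index=table.data.index, name=trait)
    usable = y.notna() & age.notna()
    for key, grp in table.data.groupby(list(group_cols), observed=True, sort=False):
        idx = grp.index[usable.loc[grp.index]]
        if len(idx) < 3:
            raise ValueError(
                f"group {key!r} has only {len(idx)} usable observations (need >= 3)"
            )
        yv = y.loc[idx].to_numpy()
        av = age.loc[idx].to_numpy()
        if np.ptp(av) == 0:
            warnings.warn(
                f"group {key!r} has zero age variance; falling back to mean-centering",
                stacklevel=2,
            )
            resid = yv - yv.mean()
        else:
            X = np.column_stack([np.ones_like(av), av])
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            resid = yv - X @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {key!r} has zero residual variance")
        out.loc[idx] = resid / sd
    return out


def adjust_all(table: PhenotypeTable, group_cols=DEFAULT_GROUP_COLS) -> pd.DataFrame:
    """Apply :func:`adjust_and_standardize` to every trait; one column each."""
    return pd.DataFrame(
        {t: adjust_and_standardize(table, t, group_cols) for t in table.trait_names}
    )
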