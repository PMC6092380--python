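"""Phenotype derivation, covariate correction, divergent-family selection, qPCR math.

The analysis unit for family selection is the family mean.  Body-weight
correction follows standard practice for composition traits: muscle yield
and fat are regressed on whole-body weight (plus any categorical covariates
supplied) and the OLS residuals are ranked instead of the raw values, so the
selected contrast is not confounded by growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Traits ranked on WBW-corrected residuals; the rest are ranked raw.
CORRECTED_TRAITS = frozenset({"muscle_yield", "fat"})


@dataclass
class ContrastDesign:
    trait: str
    high: list[str]
    low: list[str]
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.high or not self.low:
            raise ValueError("high/low family sets must be non-empty")
        if set(self.high) & set(self.low):
            raise ValueError("high and low family sets overlap")


def whiteness_index(L, a, b):
    """Fillet whiteness from CIELAB readings: 100 - sqrt((100-L)^2 + a^2 + b^2).

    Accepts scalars or arrays; maximal value 100 is attained only at
    (L, a, b) = (100, 0, 0).
    """
    L, a, b = np.asarray(L, float), np.asarray(a, float), np.asarray(b, float)
    if not (np.isfinite(L).all() and np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("whiteness_index requires finite L*, a*, b*")
    out = 100.0 - np.sqrt((100.0 - L) ** 2 + a**2 + b**2)
    return float(out) if out.ndim == 0 else out


def correct_for_covariate(
    y, covariates: pd.DataFrame | dict, categorical: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """OLS-correct a trait for covariates; returns (residuals, R^2).

    ``covariates`` holds numeric columns (e.g. WBW) and, optionally, columns
    named in ``categorical`` which are dummy-encoded as fixed effects.
    Raises on missing values or a rank-deficient design, naming the
    collinear columns.
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(covariates).copy()
    if len(X) != len(y):
        raise ValueError("y and covariates have different lengths")
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values are not allowed")
    categorical = categorical or []
    for col in categorical:
        dummies = pd.get_dummies(X[col].astype(str), prefix=col, drop_first=True, dtype=float)
        X = pd.concat([X.drop(columns=[col]), dummies], axis=1)
    X = X.astype(float)
    design = sm.add_constant(X, has_constant="add")
    if len(y) < design.shape[1] + 1:
        raise ValueError("need at least n_parameters + 1 observations")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns among {list(design.columns)}")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.resid), float(fit.rsquared)


def rank_and_select_families(
    values: dict[str, float] | pd.Series, k: int = 4, trait: str = "trait",
    covariates: list[str] | None = None,
) -> ContrastDesign:
    """Top-k and bottom-k families by trait value; ties break on family id.

    Ranking is descending; deterministic regardless of input order.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2 * k:
        raise ValueError(f"need at least {2 * k} families, got {len(s)}")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("non-finite trait values")
    order = sorted(s.index, key=lambda fid: (-s[fid], str(fid)))
    return ContrastDesign(
        trait=trait, high=list(order[:k]), low=list(order[-k:]),
        covariates=covariates or [],
    )


def ddct_fold_change(
    ct_target_test: float, ct_ref_test: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-((dCt_test) - (dCt_ctrl))."""
    vals = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def select_for_trait(
    table: pd.DataFrame, trait: str, k: int = 4, wbw_column: str = "WBW"
) -> ContrastDesign:
    """Family selection as run in the pipeline: correct yield/fat for WBW first.

    ``table`` has one row per family (or per fish; rows are averaged per
    ``family`` column when present).
    """
    df = table.copy()
    if "family" in df.columns:
        df = df.groupby("family", sort=True).mean(numeric_only=True)
    if trait not in df.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    if trait in CORRECTED_TRAITS and wbw_column in df.columns:
        resid, _ = correct_for_covariate(df[trait].to_numpy(), {wbw_column: df[wbw_column]})
        values = pd.Series(resid, index=df.index)
        covs = [wbw_column]
    else:
        values = df[trait]
        covs = []
    return rank_and_select_families(values, k=k, trait=trait, covariates=covs)
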