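"""Pollinator host-choice statistics.

Two analyses quantify how moth species composition on a tree relates to
the tree's genotype and its position in the hybrid zone: a Pearson
product-moment correlation between hybrid index and transect distance
(the two predictors are strongly collinear in a clinal zone), and a
binomial logistic regression of per-tree moth species counts on hybrid
index and distance — frequency(eastern species) ~ q + distance — fitted
by IRLS.  The per-tree aggregated-counts encoding and a per-moth
Bernoulli long format give identical binomial estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PearsonResult", "pearson_q_distance", "host_choice_glm", "SeparationError"]


class SeparationError(RuntimeError):
    """Raised when the logistic fit diverges from complete separation."""


@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    df: int
    p: float


def pearson_q_distance(records: pd.DataFrame) -> PearsonResult:
    """Pearson correlation between hybrid index ``q`` and ``distance``.

    Returns r, the t statistic ``r * sqrt(df / (1 - r^2))`` with
    df = n - 2, and the two-sided p value.
    """
    q = records["q"].to_numpy(dtype=float)
    d = records["distance"].to_numpy(dtype=float)
    n = len(q)
    if n < 3:
        raise ValueError("need at least 3 records")
    if np.var(q) == 0 or np.var(d) == 0:
        raise ValueError("zero variance in q or distance")
    r = float(np.corrcoef(q, d)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return PearsonResult(r, float("inf") * np.sign(r), df, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(t), df)
    return PearsonResult(r, float(t), df, float(p))


def host_choice_glm(
    records: pd.DataFrame,
    east_col: str = "n_antithetica",
    west_col: str = "n_synthetica",
) -> pd.DataFrame:
    """Binomial GLM of moth species frequency on tree genotype and location.

    Rows need columns ``q``, ``distance`` and the two species counts;
    trees with zero trapped moths are dropped.  Returns a coefficient
    table (estimate, se, z, p) indexed by term.  Complete separation is
    reported as an explicit error rather than a silent huge estimate;
    strong collinearity between q and distance yields a warning only.
    """
    df = records.loc[(records[east_col] + records[west_col]) > 0].copy()
    if len(df) < 3:
        raise ValueError("need at least 3 trees with trapped moths")
    exog = sm.add_constant(df[["q", "distance"]].astype(float), has_constant="add")
    cond = np.linalg.cond(np.asarray(exog))
    if cond > 1e8:
        warnings.warn(
            f"predictors nearly collinear (condition number {cond:.3g})", stacklevel=2
        )
    endog = df[[east_col, west_col]].to_numpy(dtype=float)
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except (RuntimeWarning, PerfectSeparationWarning, PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed to converge cleanly: {exc}") from exc
    if np.any(np.abs(res.params) > 1e3) or np.any(~np.isfinite(res.bse)):
        raise SeparationError("complete separation: diverging coefficient estimates")
    out = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    out.index = ["intercept", "q", "distance"]
    return out
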