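"""Dependence-adjusted correlation via random-intercept mixed models.

Slices from the same patient are correlated, so ordinary Pearson correlation
overstates the evidence.  Each factor x is related to the outcome y (DLA) by

    y_ij = beta0 + beta1 * x_ij + b_j + eps_ij,

with a Gaussian patient random intercept ``b_j`` and residual ``eps_ij``.
The dependence-adjusted correlation coefficient is

    r = beta1_hat * sqrt( var(x) / var(y) )

with plain sample variances (computed ignoring grouping).  Estimation is by
maximum likelihood (not REML) so the Wald test on beta1 is standard; with a
single group the model degenerates to ordinary least squares, in which case
r is exactly the Pearson correlation.  No multiplicity correction is applied
across factors — each factor is screened marginally at p < 0.05, so the
family-wise error over 19 screens is larger than 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["CorrelationResult", "fit_random_intercept", "correlation_screen"]

ALPHA = 0.05


@dataclass
class CorrelationResult:
    factor: str
    beta0: float
    beta1: float
    sigma_b2: float  # random-intercept variance
    sigma_e2: float  # residual variance
    r: float  # dependence-adjusted correlation
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _adjusted_r(beta1: float, x: np.ndarray, y: np.ndarray) -> float:
    r = beta1 * np.sqrt(np.var(x, ddof=1) / np.var(y, ddof=1))
    if abs(r) > 1.0:
        warnings.warn(
            f"dependence-adjusted r = {r:.4f} outside [-1, 1]; clipping",
            RuntimeWarning, stacklevel=3,
        )
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def fit_random_intercept(x, y, groups, factor: str = "x") -> CorrelationResult:
    """ML fit of the random-intercept model and the adjusted correlation.

    Requires non-degenerate x and y; with fewer than two groups the random
    intercept is unidentifiable and the fit degenerates to OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError(f"zero variance in {'x' if np.var(x) == 0 else 'y'}")

    exog = sm.add_constant(x)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        fit = sm.OLS(y, exog).fit()
        beta0, beta1 = fit.params
        p = float(fit.pvalues[1])
        sigma_b2, sigma_e2 = 0.0, float(fit.scale)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = MixedLM(y, exog, groups=groups)
            try:
                fit = model.fit(reml=False)
            except Exception as exc:  # optimizer failure
                raise RuntimeError(f"mixed-model fit failed for {factor}: {exc}") from exc
        if not np.all(np.isfinite(fit.params)):
            raise RuntimeError(f"mixed-model fit did not converge for {factor}")
        beta0, beta1 = fit.fe_params
        p = float(fit.pvalues[1])  # Wald test on beta1
        sigma_b2 = float(np.squeeze(fit.cov_re))
        sigma_e2 = float(fit.scale)

    return CorrelationResult(
        factor=factor, beta0=float(beta0), beta1=float(beta1),
        sigma_b2=sigma_b2, sigma_e2=sigma_e2,
        r=_adjusted_r(float(beta1), x, y), p_value=p,
    )


def correlation_screen(
    table: pd.DataFrame,
    response: str = "dla",
    factors: list[str] | None = None,
    group_col: str = "patient_id",
) -> pd.DataFrame:
    """One adjusted-correlation fit per factor against the response.

    Returns a DataFrame with columns factor, beta1, r, p_value, significant
    (p < 0.05, uncorrected — matching a marginal screen).
    """
    from .features import FACTOR_COLUMNS

    factors = factors if factors is not None else FACTOR_COLUMNS
    y = table[response].to_numpy()
    groups = table[group_col].to_numpy()
    rows = []
    for name in factors:
        res = fit_random_intercept(table[name].to_numpy(), y, groups, factor=name)
        rows.append(
            dict(factor=name, beta0=res.beta0, beta1=res.beta1,
                 sigma_b2=res.sigma_b2, sigma_e2=res.sigma_e2,
                 r=res.r, p_value=res.p_value, significant=res.significant)
        )
    return pd.DataFrame(rows)
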