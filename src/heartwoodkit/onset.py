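"""Heartwood-onset estimation from logistic occurrence models.

The probability that a stem cross-section already contains heartwood is
modelled as a logistic function of the natural log of stem diameter or
cambial age, optionally with a covariate (site indicator or log growth
rate):

    P = logistic(a + b * ln(x) [+ c * z])

The onset threshold is the inflection point of the fitted response —
the diameter or age at which P = 0.5 — i.e. ``exp(-(a + c z) / b)``,
with a delta-method (default) or parametric-bootstrap confidence
interval on the log-threshold. Nested models are compared by likelihood
ratio.

Fitting is maximum likelihood via iteratively reweighted least squares
(statsmodels GLM, binomial family), deviance tolerance 1e-10, at most
100 iterations. Complete separation is reported as a non-converged fit
with a diagnostic rather than as a silent success.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PREDICTOR_SPECS",
    "LogisticFit",
    "OnsetThreshold",
    "OccurrenceModel",
    "fit_occurrence",
    "onset_threshold",
    "covariate_lrt",
]

#: predictor_spec -> (log-predictor column, covariate column or None)
PREDICTOR_SPECS = {
    "logD": ("diameter", None),
    "logAge": ("age", None),
    "logD+site": ("diameter", "site"),
    "logAge+logGR": ("age", "log_gr"),
}

_SEPARATION_COEF_BOUND = 1e3


@dataclass
class LogisticFit:
    """A fitted occurrence model.

    ``coefficients`` is ordered (a, b[, c]): intercept, slope on the
    log predictor, optional covariate coefficient. ``vcov`` is the
    ML coefficient covariance (symmetric PSD).
    """

    predictor_spec: str
    coefficients: np.ndarray
    vcov: np.ndarray
    loglik: float
    n: int
    converged: bool
    diagnostic: str = ""

    @property
    def a(self) -> float:
        return float(self.coefficients[0])

    @property
    def b(self) -> float:
        return float(self.coefficients[1])

    @property
    def c(self) -> float | None:
        return float(self.coefficients[2]) if len(self.coefficients) > 2 else None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def predict(self, x, z=None) -> np.ndarray:
        """P(heartwood present) at predictor value(s) x (natural scale)."""
        eta = self.a + self.b * np.log(np.asarray(x, float))
        if self.c is not None:
            if z is None:
                raise ValueError("model has a covariate; supply z")
            eta = eta + self.c * np.asarray(z, float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class OnsetThreshold:
    """Inflection-point onset threshold on the natural (cm or years) scale."""

    scale: str
    point: float
    ci_low: float
    ci_high: float
    covariate_value: float | None
    ci_method: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("threshold CI must bracket the point estimate")
        if self.point <= 0:
            raise ValueError("threshold must be positive")


class OccurrenceModel(BaseEstimator):
    """Sklearn-style logistic heartwood-occurrence estimator.

    Parameters
    ----------
    covariate : bool
        Whether the design includes a covariate column.
    predictor_spec : str
        Label recorded on the fit (one of :data:`PREDICTOR_SPECS` or a
        custom description).

    Attributes (after fit)
    ----------------------
    fit_ : LogisticFit
    coefficients_, vcov_, loglik_ : convenience aliases
    """

    def __init__(self, covariate: bool = False, predictor_spec: str = "logAge"):
        self.covariate = covariate
        self.predictor_spec = predictor_spec

    def fit(self, X, y):
        """Fit to X = column-stack of (predictor x, [covariate z]); y binary.

        The log transform of the first column is applied here; the
        covariate enters untransformed (pass log GR yourself for the
        growth-rate specification).
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and X.shape[1] > 2:
            X = X.T
        y = np.asarray(y, float)
        x = X[:, 0]
        if np.any(x <= 0):
            raise ValueError("predictor values must be strictly positive")
        if y.min() == y.max():
            raise ValueError(
                "outcome is constant (complete separation): both presence and "
                "absence are required"
            )
        cols = [np.ones_like(x), np.log(x)]
        if self.covariate:
            if X.shape[1] < 2:
                raise ValueError("covariate=True requires a second column")
            cols.append(X[:, 1])
        design = np.column_stack(cols)
        if len(y) < design.shape[1]:
            raise ValueError("fewer observations than coefficients")

        model = sm.GLM(y, design, family=sm.families.Binomial())
        converged, diagnostic = True, ""
        try:
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                res = model.fit(maxiter=100, tol=1e-10)
            separation_warned = any(
                "separation" in str(w.message).lower() for w in caught
            )
            coef = np.asarray(res.params)
            vcov = np.asarray(res.cov_params())
            loglik = float(res.llf)
            if (
                separation_warned
                or not np.all(np.isfinite(coef))
                or not np.all(np.isfinite(vcov))
                or np.max(np.abs(coef)) > _SEPARATION_COEF_BOUND
                or np.max(np.diag(vcov)) > _SEPARATION_COEF_BOUND**2
            ):
                converged = False
                diagnostic = (
                    "diverging coefficients: data are (quasi-)completely separated"
                )
        except Exception as exc:  # statsmodels PerfectSeparation*, LinAlgError
            converged = False
            diagnostic = f"fit failed: {exc}"
            p = design.shape[1]
            coef = np.full(p, np.nan)
            vcov = np.full((p, p), np.nan)
            loglik = np.nan

        self.fit_ = LogisticFit(
            predictor_spec=self.predictor_spec,
            coefficients=coef,
            vcov=vcov,
            loglik=loglik,
            n=len(y),
            converged=converged,
            diagnostic=diagnostic,
        )
        self.coefficients_ = coef
        self.vcov_ = vcov
        self.loglik_ = loglik
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        p = self.fit_.predict(X[:, 0], X[:, 1] if self.covariate else None)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_occurrence(records: pd.DataFrame, spec: str) -> LogisticFit:
    """Fit one of the four occurrence-model specifications to a disc table.

    ``records`` needs columns ``hw_present`` plus, depending on spec:
    ``diameter`` (or ``S_R``, doubled), ``cambial_age``, ``GR``,
    ``cohort``. Site is coded shaded = 0, sun_exposed = 1.
    """
    if spec not in PREDICTOR_SPECS:
        raise ValueError(f"unknown predictor spec {spec!r}")
    pred, cov = PREDICTOR_SPECS[spec]
    df = records
    if pred == "diameter":
        x = (
            df["diameter"].to_numpy(float)
            if "diameter" in df
            else 2.0 * df["S_R"].to_numpy(float)
        )
    else:
        x = df["cambial_age"].to_numpy(float)
    if cov is None:
        X = x[:, None]
    elif cov == "site":
        z = (df["cohort"].astype(str) == "sun_exposed").to_numpy(float)
        X = np.column_stack([x, z])
    else:  # log growth rate
        gr = df["GR"].to_numpy(float)
        if np.any(gr <= 0):
            raise ValueError("growth rates must be positive")
        X = np.column_stack([x, np.log(gr)])
    est = OccurrenceModel(covariate=cov is not None, predictor_spec=spec)
    est.fit(X, df["hw_present"].to_numpy(float))
    return est.fit_


def onset_threshold(
    fit: LogisticFit,
    covariate_value: float | None = None,
    alpha: float = 0.05,
    ci_method: str = "delta",
    n_boot: int = 2000,
    random_state: int | None = 0,
) -> OnsetThreshold:
    """Onset threshold (P = 0.5) with confidence interval.

    point = exp(-(a + c z) / b). The delta method propagates the
    coefficient covariance through theta = -(a + c z)/b and
    exponentiates the interval; the parametric bootstrap redraws
    coefficients from N(coef, vcov).
    """
    if not fit.converged:
        raise ValueError(f"cannot derive a threshold from a non-converged fit: {fit.diagnostic}")
    a, b, c = fit.a, fit.b, fit.c
    se_b = fit.se()[1]
    if abs(b) < 1e-8 * max(se_b, 1e-12):
        raise ValueError("slope indistinguishable from zero: threshold unidentifiable")
    z = 0.0 if covariate_value is None else float(covariate_value)
    if c is None and covariate_value is not None:
        raise ValueError("fit has no covariate; covariate_value must be None")
    shift = a + (c * z if c is not None else 0.0)
    theta = -shift / b

    zcrit = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delta":
        grad = [-1.0 / b, shift / b**2]
        if c is not None:
            grad.append(-z / b)
        g = np.asarray(grad)
        var = float(g @ fit.vcov @ g)
        half = zcrit * np.sqrt(var)
        lo, hi = np.exp(theta - half), np.exp(theta + half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(random_state)
        draws = rng.multivariate_normal(fit.coefficients, fit.vcov, size=n_boot)
        shift_d = draws[:, 0] + (draws[:, 2] * z if c is not None else 0.0)
        theta_d = -shift_d / draws[:, 1]
        lo, hi = np.exp(
            np.quantile(theta_d, [alpha / 2, 1 - alpha / 2])
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    scale = "cm" if fit.predictor_spec.startswith("logD") else "years"
    return OnsetThreshold(
        scale=scale,
        point=float(np.exp(theta)),
        ci_low=float(min(lo, np.exp(theta))),
        ci_high=float(max(hi, np.exp(theta))),
        covariate_value=covariate_value,
        ci_method=ci_method,
    )


def covariate_lrt(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested occurrence models.

    Returns (chi2, df, p) with chi2 = 2 (ll_full - ll_reduced) and df
    the coefficient-count difference.
    """
    if full.n != reduced.n:
        raise ValueError("models were fitted to different records")
    df = len(full.coefficients) - len(reduced.coefficients)
    if df < 0:
        raise ValueError("'full' has fewer coefficients than 'reduced': not nested")
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        return chi2, 0, 1.0
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p
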