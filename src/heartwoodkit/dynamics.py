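"""Candidate heartwood-dynamics models, RSE selection and nested tests.

Heartwood quantities (area, areal proportion, ring count) are regressed
on stem diameter or cambial age with four candidate mean functions:

* linear        y = a0 + a1 x
* quadratic     y = a0 + a1 x + a2 x^2
* power         y = a0 * x ** a1
* asym_exp      y = a0 + (a1 - a0) * exp(-a2 x)   (a0 asymptote,
                a1 intercept at x = 0, a2 > 0 relative rate)

All are fitted by least squares; the nonlinear families use a small set
of deterministic data-driven starts (no randomness). Among converged
fits the family with the lowest residual standard error
``rse = sqrt(RSS / (n - p))`` is selected, ties going to the family
with fewer parameters. Group differences are tested with the Gaussian
likelihood-ratio statistic ``n ln(RSS_shared / RSS_group)``. The
x-intercept of the linear ring-count fit gives the age at which the
first ring is converted to heartwood, with a delta-method CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FAMILIES",
    "CandidateFit",
    "ModelSelection",
    "CandidateCurve",
    "fit_family",
    "select_model",
    "group_lrt",
    "first_ring_age",
]

#: fixed family order used for deterministic tie-breaking
FAMILIES = ("linear", "quadratic", "power", "asym_exp")

_N_PARAMS = {"linear": 2, "quadratic": 3, "power": 2, "asym_exp": 3}


@dataclass
class CandidateFit:
    """One fitted candidate family."""

    family: str
    params: np.ndarray
    param_ses: np.ndarray
    rse: float
    n: int
    converged: bool
    loglik: float
    rss: float
    vcov: np.ndarray | None = None


def _curve(family: str, x: np.ndarray, params: np.ndarray) -> np.ndarray:
    if family == "linear":
        return params[0] + params[1] * x
    if family == "quadratic":
        return params[0] + params[1] * x + params[2] * x**2
    if family == "power":
        return params[0] * x ** params[1]
    if family == "asym_exp":
        a0, a1, log_a2 = params
        rate = np.exp(min(log_a2, 50.0))
        return a0 + (a1 - a0) * np.exp(-np.minimum(rate * x, 700.0))
    raise ValueError(f"unknown family {family!r}")


def _starts(family: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic data-driven multistart values (internal scale)."""
    if family == "power":
        pos = (x > 0) & (y > 0)
        if pos.sum() >= 2:
            b, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            base = [np.exp(loga), b]
        else:
            base = [1.0, 1.0]
        return [
            np.array(base),
            np.array([max(np.mean(y), 1e-6), 1.0]),
            np.array([base[0], base[1] * 0.5]),
            np.array([base[0] * 2.0, base[1]]),
            np.array([max(y.max() / max(x.max() ** 2, 1e-12), 1e-9), 2.0]),
        ]
    if family == "asym_exp":
        a0 = float(y.max() + 0.05 * abs(np.ptp(y)))
        a1 = float(y.min())
        span = max(np.ptp(x), 1e-6)
        rates = [1.0 / span, 3.0 / span, 0.3 / span, 10.0 / span, 1.0]
        return [np.array([a0, a1, np.log(r)]) for r in rates]
    raise ValueError(family)


def _linear_ls(x: np.ndarray, y: np.ndarray, degree: int):
    """Polynomial least squares with classical vcov; params low->high order."""
    X = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n, p = len(y), degree + 1
    sigma2 = rss / (n - p) if n > p else np.nan
    vcov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, vcov, rss


class CandidateCurve(BaseEstimator, RegressorMixin):
    """Sklearn-style least-squares fit of one candidate family.

    Attributes after fit: ``params_`` (natural scale: for asym_exp the
    rate a2 itself, not its log), ``param_ses_``, ``rse_``,
    ``loglik_``, ``converged_``, ``fit_``.
    """

    def __init__(self, family: str = "power"):
        self.family = family

    def fit(self, X, y):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        n, p = x.size, _N_PARAMS[self.family]
        if n < p + 1:
            raise ValueError(f"{self.family} needs at least {p + 1} observations")

        if self.family in ("linear", "quadratic"):
            deg = 1 if self.family == "linear" else 2
            coef, vcov, rss = _linear_ls(x, y, deg)
            params, ses = coef, np.sqrt(np.diag(vcov))
            converged = True
        else:
            if self.family == "power" and (np.any(x <= 0) or np.any(y <= 0)):
                raise ValueError("power family requires positive x and y")
            best = None
            for start in _starts(self.family, x, y):
                try:
                    res = optimize.least_squares(
                        lambda th: _curve(self.family, x, th) - y,
                        start,
                        method="lm",
                        xtol=1e-12,
                        ftol=1e-12,
                        max_nfev=5000,
                    )
                except Exception:
                    continue
                rss_c = float(2 * res.cost)
                if np.all(np.isfinite(res.x)) and (best is None or rss_c < best[1]):
                    best = (res, rss_c)
            if best is None:
                raise RuntimeError(f"{self.family} fit failed from every start")
            res, rss = best
            converged = bool(best[0].status > 0)
            theta = res.x
            # vcov on the internal scale via the Jacobian at the optimum
            J = res.jac
            sigma2 = rss / (n - p)
            try:
                vcov_int = sigma2 * np.linalg.inv(J.T @ J)
            except np.linalg.LinAlgError:
                vcov_int = np.full((p, p), np.nan)
                converged = False
            if self.family == "asym_exp":
                # report the rate a2 = exp(log_a2); delta method for its SE
                a2 = float(np.exp(theta[2]))
                grad = np.diag([1.0, 1.0, a2])
                vcov = grad @ vcov_int @ grad
                params = np.array([theta[0], theta[1], a2])
            else:
                params, vcov = theta, vcov_int
            ses = np.sqrt(np.abs(np.diag(vcov)))

        rse = float(np.sqrt(rss / (n - p)))
        # Gaussian profile log-likelihood at the ML variance rss/n
        loglik = (
            -0.5 * n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1.0)
        )
        self.params_ = np.asarray(params, float)
        self.param_ses_ = np.asarray(ses, float)
        self.rse_, self.loglik_, self.converged_ = rse, float(loglik), converged
        self.rss_, self.n_ = float(rss), n
        self.vcov_ = np.asarray(vcov, float)
        self.fit_ = CandidateFit(
            family=self.family,
            params=self.params_,
            param_ses=self.param_ses_,
            rse=rse,
            n=n,
            converged=converged,
            loglik=float(loglik),
            rss=float(rss),
            vcov=self.vcov_,
        )
        return self

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        th = self.params_.copy()
        if self.family == "asym_exp":
            th = np.array([th[0], th[1], np.log(th[2])])
        return _curve(self.family, x, th)


def fit_family(family: str, x, y, groups=None):
    """Fit one family, optionally per group plus shared.

    With ``groups`` given, returns ``(shared_fit, {label: fit})``;
    otherwise a single :class:`CandidateFit`.
    """
    if groups is None:
        return CandidateCurve(family).fit(x, y).fit_
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    g = np.asarray(groups)
    shared = CandidateCurve(family).fit(x, y).fit_
    per_group = {
        str(label): CandidateCurve(family).fit(x[g == label], y[g == label]).fit_
        for label in np.unique(g)
    }
    return shared, per_group


@dataclass
class ModelSelection:
    fits: list[CandidateFit]
    chosen: str
    criterion: str = "rse"


def select_model(fits) -> ModelSelection:
    """Choose the converged fit with minimal RSE.

    Ties (within 1e-12 relative) break toward fewer parameters, then
    the fixed family order of :data:`FAMILIES`.
    """
    fits = list(fits)
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to select from")
    best_rse = min(f.rse for f in conv)
    # absolute floor so that exact (numerically-zero) fits of nested
    # families count as ties and resolve toward fewer parameters
    tied = [f for f in conv if f.rse <= best_rse + max(1e-10, 1e-9 * best_rse)]
    tied.sort(key=lambda f: (len(f.params), FAMILIES.index(f.family)))
    return ModelSelection(fits=fits, chosen=tied[0].family)


def group_lrt(shared_fit: CandidateFit, group_fits) -> tuple[float, int, float]:
    """Gaussian LRT of a per-group model against a shared model.

    chi2 = n * ln(RSS_shared / RSS_groups); df = extra parameters.
    """
    group_fits = list(group_fits.values()) if isinstance(group_fits, dict) else list(group_fits)
    if any(f.family != shared_fit.family for f in group_fits):
        raise ValueError("group fits must use the shared fit's family (nesting)")
    n_g = sum(f.n for f in group_fits)
    if n_g != shared_fit.n:
        raise ValueError("group fits do not partition the shared fit's records")
    rss_group = sum(f.rss for f in group_fits)
    df = sum(len(f.params) for f in group_fits) - len(shared_fit.params)
    if df <= 0:
        raise ValueError("group model does not add parameters: not nested")
    chi2 = max(shared_fit.n * np.log(shared_fit.rss / rss_group), 0.0)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def first_ring_age(
    linear_fit: CandidateFit,
    crossing: float = 0.0,
    alpha: float = 0.05,
    ci_method: str = "delta",
    n_boot: int = 2000,
    random_state: int | None = 0,
) -> tuple[float, tuple[float, float]]:
    """Age at which the linear ring-count fit crosses ``crossing`` rings.

    For y = a0 + a1 x the estimate is (crossing - a0) / a1, the age at
    which the first ring is converted into heartwood (crossing 0 by
    default; crossing 1 treats "one full ring" as the event). CI by the
    delta method on the ratio, or by a parametric bootstrap from
    N(params, vcov).
    """
    if linear_fit.family != "linear":
        raise ValueError("first_ring_age requires a linear fit")
    a0, a1 = linear_fit.params[:2]
    if a1 <= 0:
        raise ValueError("ring-conversion rate a1 must be positive")
    point = (crossing - a0) / a1
    V = linear_fit.vcov
    if ci_method == "delta":
        g = np.array([-1.0 / a1, -(crossing - a0) / a1**2])
        var = float(g @ V[:2, :2] @ g)
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(var)
        ci = (point - half, point + half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(random_state)
        draws = rng.multivariate_normal([a0, a1], V[:2, :2], size=n_boot)
        vals = (crossing - draws[:, 0]) / draws[:, 1]
        vals = vals[draws[:, 1] > 0]
        ci = tuple(np.quantile(vals, [alpha / 2, 1 - alpha / 2]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return float(point), (float(ci[0]), float(ci[1]))
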