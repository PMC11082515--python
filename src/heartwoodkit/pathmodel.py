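"""Recursive path analysis of age vs hydraulic drivers of heartwood.

The system is a two-equation recursive (acyclic) Gaussian model on
z-scored variables:

    mediator  M = p1 * Age + p2 * Hyd          + e1
    outcome   Y = p3 * M  + p4 * Age + p5 * Hyd + e2

with M the stem diameter, Y the heartwood area (trunk level) or sapwood
area (branch level) and Hyd the total conductive vessel area (trunk) or
total leaf area (branch). For a recursive Gaussian system equation-wise
least squares is the maximum-likelihood estimator, so each equation is
fitted by OLS on the z-scored variables.

Because the coefficients are standardized, their sampling variability
includes the randomness of the standardizing scales; the classical
per-equation OLS covariance ignores this and is anticonservative for
contrasts. The joint coefficient covariance is therefore obtained by
normal-theory propagation: the coefficients are a smooth function of
the sample covariance matrix S, whose asymptotic covariance under
normality is cov(s_ij, s_kl) = (s_ik s_jl + s_il s_jk) / n; the
delta method through the coefficient map gives the 5x5 joint
covariance used for all standard errors and Wald contrasts.

Effects of each exogenous variable on the outcome decompose exactly as

    direct    = its own path to Y            (p4 or p5)
    indirect  = path to M  *  M's path to Y  (p1*p3 or p2*p3)
    total     = direct + indirect

Standard errors of products come from the delta method on the joint
covariance; contrasts between any two effects are Wald chi-square tests
with the full effect covariance (shared parameters induce covariance
between, e.g., the two indirect effects through p3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["PathSpec", "PathModel", "WaldContrast", "PathAnalyzer", "fit_path", "wald_contrast"]

_PARAM_NAMES = ("age_to_mediator", "hyd_to_mediator", "mediator_to_outcome",
                "age_to_outcome", "hyd_to_outcome")

_EFFECTS = {
    # effect -> (linear index or product indices) into the 5-vector
    ("age", "direct"): (3,),
    ("hyd", "direct"): (4,),
    ("mediator", "direct"): (2,),
    ("age", "indirect"): (0, 2),
    ("hyd", "indirect"): (1, 2),
}


@dataclass(frozen=True)
class PathSpec:
    """Variable roles: column names in the data table."""

    mediator: str = "D"
    outcome: str = "HWa"
    exogenous: tuple[str, str] = ("Age", "TCVA")


@dataclass
class PathModel:
    """Fitted standardized recursive path system."""

    spec: PathSpec
    coefficients: np.ndarray  # (p1, p2, p3, p4, p5)
    vcov: np.ndarray  # 5x5 joint covariance (normal-theory delta method)
    effects: pd.DataFrame  # source, kind, estimate, se, p
    exog_corr: float
    n: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[_PARAM_NAMES.index(name)])

    def effect(self, source: str, kind: str) -> tuple[float, float]:
        """(estimate, se) of one row of the effects table."""
        row = self.effects[
            (self.effects["source"] == source) & (self.effects["kind"] == kind)
        ]
        if row.empty:
            raise KeyError(f"no {kind} effect for {source!r}")
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])

    def _effect_gradient(self, source: str, kind: str) -> np.ndarray:
        """Gradient of the named effect w.r.t. the 5 path coefficients."""
        g = np.zeros(5)
        if kind == "total":
            for k in ("direct", "indirect"):
                g += self._effect_gradient(source, k)
            return g
        idx = _EFFECTS[(source, kind)]
        if len(idx) == 1:
            g[idx[0]] = 1.0
        else:
            i, j = idx
            g[i] = self.coefficients[j]
            g[j] = self.coefficients[i]
        return g

    def _effect_value(self, source: str, kind: str) -> float:
        if kind == "total":
            return self._effect_value(source, "direct") + self._effect_value(
                source, "indirect"
            )
        idx = _EFFECTS[(source, kind)]
        return float(np.prod(self.coefficients[list(idx)]))


@dataclass
class WaldContrast:
    description: str
    statistic: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("Wald statistic must be non-negative")


class PathAnalyzer(BaseEstimator):
    """Sklearn-style estimator for the two-equation recursive path system.

    Parameters
    ----------
    spec : PathSpec
        Column roles; defaults to the trunk-level Age/TCVA -> D -> HWa
        system.
    condition_threshold : float
        Collinearity guard on the standardized design.

    Attributes after fit: ``model_`` (:class:`PathModel`),
    ``coefficients_``, ``effects_``.
    """

    def __init__(self, spec: PathSpec | None = None, condition_threshold: float = 1e8):
        self.spec = spec
        self.condition_threshold = condition_threshold

    def fit(self, X: pd.DataFrame, y=None):
        spec = self.spec if self.spec is not None else PathSpec()
        cols = [spec.exogenous[0], spec.exogenous[1], spec.mediator, spec.outcome]
        data = X[cols].dropna()
        n = len(data)
        if n < 10:
            raise ValueError(f"path analysis needs >= 10 complete cases, got {n}")
        Z = data.to_numpy(float)
        sd = Z.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"zero variance in {zero}")
        Z = (Z - Z.mean(axis=0)) / sd
        age, hyd, med, out = Z.T

        corr = np.corrcoef(np.column_stack([age, hyd, med]).T)
        off = np.abs(corr[np.triu_indices(3, 1)])
        if np.any(off > 1 - 1e-9):
            pairs = [("age", "hyd"), ("age", "mediator"), ("hyd", "mediator")]
            bad = pairs[int(np.argmax(off))]
            raise ValueError(f"collinear predictors: {bad[0]} vs {bad[1]}")

        if max(
            np.linalg.cond(np.column_stack([age, hyd])),
            np.linalg.cond(np.column_stack([med, age, hyd])),
        ) > self.condition_threshold:
            raise ValueError("ill-conditioned design: predictors nearly collinear")

        S = np.cov(np.column_stack([age, hyd, med, out]).T, ddof=1)
        coef = _theta_from_cov(S)  # (p1, p2, p3, p4, p5)
        V = _normal_theory_vcov(S, n)

        model = PathModel(
            spec=spec,
            coefficients=coef,
            vcov=V,
            effects=pd.DataFrame(),
            exog_corr=float(np.corrcoef(age, hyd)[0, 1]),
            n=n,
        )
        rows = []
        for source in ("age", "hyd"):
            for kind in ("direct", "indirect", "total"):
                est = model._effect_value(source, kind)
                g = model._effect_gradient(source, kind)
                se = float(np.sqrt(g @ V @ g))
                z = est / se if se > 0 else np.inf * np.sign(est)
                rows.append(
                    {
                        "source": source,
                        "kind": kind,
                        "estimate": est,
                        "se": se,
                        "p": float(2 * stats.norm.sf(abs(z))),
                    }
                )
        est, gse = model.coef("mediator_to_outcome"), float(np.sqrt(V[2, 2]))
        rows.append(
            {
                "source": "mediator",
                "kind": "direct",
                "estimate": est,
                "se": gse,
                "p": float(2 * stats.norm.sf(abs(est / gse))) if gse > 0 else 0.0,
            }
        )
        model.effects = pd.DataFrame(rows)
        self.model_ = model
        self.coefficients_ = coef
        self.effects_ = model.effects
        return self


def _theta_from_cov(S: np.ndarray) -> np.ndarray:
    """Standardized path coefficients as a function of the covariance
    matrix of (age, hyd, mediator, outcome) — the normal equations on
    the implied correlation matrix."""
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    b1 = np.linalg.solve(R[:2, :2], R[:2, 2])
    idx = [2, 0, 1]
    b2 = np.linalg.solve(R[np.ix_(idx, idx)], R[idx, 3])
    return np.concatenate([b1, b2])


def _normal_theory_vcov(S: np.ndarray, n: int, eps: float = 1e-6) -> np.ndarray:
    """Delta-method covariance of the standardized coefficients.

    Propagates the asymptotic covariance of the sample covariance
    matrix, cov(s_ij, s_kl) = (s_ik s_jl + s_il s_jk)/n, through the
    coefficient map with a central-difference Jacobian.
    """
    k = S.shape[0]
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    G = np.empty((5, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        step = eps * np.sqrt(S[i, i] * S[j, j])
        E = np.zeros_like(S)
        E[i, j] = E[j, i] = step
        G[:, col] = (_theta_from_cov(S + E) - _theta_from_cov(S - E)) / (2 * step)
    W = np.empty((len(pairs), len(pairs)))
    for a, (i, j) in enumerate(pairs):
        for b, (kk, ll) in enumerate(pairs):
            W[a, b] = (S[i, kk] * S[j, ll] + S[i, ll] * S[j, kk]) / n
    return G @ W @ G.T


def fit_path(data: pd.DataFrame, spec: PathSpec | None = None) -> PathModel:
    """Fit the recursive path system to a data table (see :class:`PathAnalyzer`)."""
    return PathAnalyzer(spec=spec).fit(data).model_


def wald_contrast(
    model: PathModel,
    effect_a: tuple[str, str],
    effect_b: tuple[str, str],
) -> WaldContrast:
    """Wald chi-square test of equality of two effects.

    Effects are named as (source, kind) pairs, e.g. ``("age",
    "indirect")`` vs ``("hyd", "indirect")``; sources are "age", "hyd"
    or "mediator", kinds "direct", "indirect" or "total". The variance
    of the difference uses the delta method on the joint coefficient
    covariance, including the covariance the two effects share through
    common path coefficients.
    """
    ga = model._effect_gradient(*effect_a)
    gb = model._effect_gradient(*effect_b)
    diff = model._effect_value(*effect_a) - model._effect_value(*effect_b)
    g = ga - gb
    if np.allclose(g, 0) and diff == 0:  # an effect contrasted with itself
        return WaldContrast(
            description=f"{effect_a[0]}:{effect_a[1]} vs {effect_b[0]}:{effect_b[1]}",
            statistic=0.0,
            df=1,
            p=1.0,
        )
    var = float(g @ model.vcov @ g)
    if var <= 0:
        raise ValueError("zero variance of the effect difference")
    statistic = diff**2 / var
    return WaldContrast(
        description=f"{effect_a[0]}:{effect_a[1]} vs {effect_b[0]}:{effect_b[1]}",
        statistic=float(statistic),
        df=1,
        p=float(stats.chi2.sf(statistic, 1)),
    )
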