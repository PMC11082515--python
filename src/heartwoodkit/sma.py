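"""Standardized major axis (SMA) line fitting for allometric scaling.

SMA treats x and y symmetrically: the slope is sign(r) * sd(y) / sd(x),
the line passes through the bivariate mean, and swapping the axes
inverts the slope. Slopes of ln-transformed variables are the scaling
exponents of power laws, which is how stem, sapwood, heartwood and
conduit tapering along the trunk are quantified here.

The slope confidence interval is the standard SMA interval
``slope * (sqrt(B + 1) +/- sqrt(B))`` with
``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)``.

The between-group common-slope test is the SMA likelihood-ratio
procedure: at a candidate common slope ``b`` the residual and axis
scores ``u = y - b x`` and ``v = y + b x`` are uncorrelated within a
group exactly when ``b`` is that group's SMA slope, so

    LR(b) = -sum_i n_i * ln(1 - r_i(b)^2),   r_i = corr(u_i, v_i),

minimised over ``b``, is asymptotically chi-square with (groups - 1)
degrees of freedom. A residual-rotation permutation reference is
available as a finite-sample cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SMAFit",
    "CommonSlopeTest",
    "SMARegressor",
    "sma_fit",
    "common_slope_test",
    "conduit_taper",
]


@dataclass
class SMAFit:
    """Fitted SMA line (on the transformed scale when log is applied)."""

    slope: float
    intercept: float
    r2: float
    n: int
    slope_ci: tuple[float, float]
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci
        if not lo <= self.slope <= hi:
            raise ValueError("slope CI must bracket the slope")


class SMARegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style standardized major axis estimator.

    Parameters
    ----------
    log_transform : bool
        Fit on natural logs of both variables (inputs must be positive).
    alpha : float
        1 - confidence level of the slope interval.

    Attributes (after fit)
    ----------------------
    slope_, intercept_, r2_, n_, slope_ci_ : the fitted line
    fit_ : SMAFit
    """

    def __init__(self, log_transform: bool = True, alpha: float = 0.05):
        self.log_transform = log_transform
        self.alpha = alpha

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 3:
            raise ValueError("SMA requires n >= 3")
        if self.log_transform:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ValueError("log transform requires strictly positive data")
            x, y = np.log(x), np.log(y)
        sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in x or y")
        r = float(np.corrcoef(x, y)[0, 1])
        if r == 0:
            raise ValueError("correlation exactly zero: SMA slope sign indeterminate")
        n = x.size
        slope = float(np.sign(r) * sy / sx)
        intercept = float(np.mean(y) - slope * np.mean(x))
        B = stats.f.ppf(1 - self.alpha, 1, n - 2) * (1 - r**2) / (n - 2)
        lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
        if slope < 0:
            lo, hi = hi, lo
        self.slope_, self.intercept_, self.r2_, self.n_ = slope, intercept, r**2, n
        self.slope_ci_ = (float(lo), float(hi))
        self.fit_ = SMAFit(slope, intercept, r**2, n, self.slope_ci_)
        return self

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        if self.log_transform:
            return np.exp(self.intercept_ + self.slope_ * np.log(x))
        return self.intercept_ + self.slope_ * x


def sma_fit(
    x,
    y,
    log_transform: bool = True,
    alpha: float = 0.05,
    x_label: str = "x",
    y_label: str = "y",
) -> SMAFit:
    """Fit a standardized major axis line; see :class:`SMARegressor`."""
    est = SMARegressor(log_transform=log_transform, alpha=alpha).fit(x, y)
    fit = est.fit_
    fit.x_label, fit.y_label = x_label, y_label
    return fit


@dataclass
class CommonSlopeTest:
    """Likelihood-ratio test of slope homogeneity across groups."""

    statistic: float
    df: int
    p: float
    group_slopes: list[float]
    common_slope: float
    p_permutation: float | None = None

    def __post_init__(self) -> None:
        if self.statistic < -1e-9:
            raise ValueError("LR statistic must be non-negative")
        self.statistic = max(self.statistic, 0.0)


def _residual_axis_corr(x: np.ndarray, y: np.ndarray, b: float) -> float:
    u = y - b * x
    v = y + b * x
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _lr_statistic(groups, b: float) -> float:
    # (n - 2.5) weighting is the usual Bartlett-type small-sample
    # correction for the SMA common-slope likelihood ratio
    stat = 0.0
    for x, y in groups:
        r = _residual_axis_corr(x, y, b)
        r = min(abs(r), 1 - 1e-12)
        stat += -max(len(x) - 2.5, 1.0) * np.log1p(-(r**2))
    return stat


def _common_slope(groups) -> tuple[float, float]:
    """Minimise the LR statistic over the common slope b."""
    slopes = []
    for x, y in groups:
        r = np.corrcoef(x, y)[0, 1]
        slopes.append(np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    lo, hi = min(slopes), max(slopes)
    span = max(hi - lo, 1e-6 * max(abs(lo), abs(hi), 1.0))
    res = optimize.minimize_scalar(
        lambda b: _lr_statistic(groups, b),
        bounds=(lo - 0.5 * span, hi + 0.5 * span),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(res.fun)


def common_slope_test(
    groups,
    log_transform: bool = False,
    n_permutations: int = 0,
    random_state: int | None = 0,
) -> CommonSlopeTest:
    """Test whether >= 2 groups share a common SMA slope.

    Parameters
    ----------
    groups : sequence of (x, y) pairs
        Each with n >= 3 and nonzero variance.
    log_transform : bool
        Apply natural logs first.
    n_permutations : int
        If > 0, also compute a residual-rotation permutation p-value:
        within each group the residual scores u = y - b x (at the
        fitted common slope) are permuted against the axis scores
        v = y + b x, the data are reconstructed and the LR statistic
        recomputed.
    """
    prepared = []
    for x, y in groups:
        x = np.asarray(x, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if x.size < 3:
            raise ValueError("each group needs n >= 3")
        if log_transform:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ValueError("log transform requires positive data")
            x, y = np.log(x), np.log(y)
        if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
            raise ValueError("degenerate group: zero variance")
        prepared.append((x, y))
    if len(prepared) < 2:
        raise ValueError("need at least two groups")

    slopes = [
        float(np.sign(np.corrcoef(x, y)[0, 1]) * np.std(y, ddof=1) / np.std(x, ddof=1))
        for x, y in prepared
    ]
    b_com, stat = _common_slope(prepared)
    df = len(prepared) - 1
    p = float(stats.chi2.sf(stat, df))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(random_state)
        exceed = 0
        for _ in range(n_permutations):
            perm_groups = []
            for x, y in prepared:
                u = y - b_com * x
                v = y + b_com * x
                u = rng.permutation(u - u.mean()) + u.mean()
                perm_groups.append(((v - u) / (2 * b_com), (u + v) / 2.0))
            _, stat_p = _common_slope(perm_groups)
            exceed += stat_p >= stat
        p_perm = (exceed + 1) / (n_permutations + 1)

    return CommonSlopeTest(
        statistic=stat,
        df=df,
        p=p,
        group_slopes=slopes,
        common_slope=b_com,
        p_permutation=p_perm,
    )


def conduit_taper(
    distance_from_top,
    d_h,
    log_transform: bool = True,
    min_distance: float = 0.5,
) -> SMAFit | None:
    """Tree-level conduit tapering: SMA slope of D_H against distance from top.

    Discs closer to the top than ``min_distance`` (m) are excluded from
    ln-ln fits, where ln(L) degenerates as L -> 0. Returns None (the
    value is missing, not zero) when fewer than three usable discs
    remain.
    """
    L = np.asarray(distance_from_top, float)
    d = np.asarray(d_h, float)
    keep = np.isfinite(L) & np.isfinite(d)
    if log_transform:
        keep &= L >= min_distance
    L, d = L[keep], d[keep]
    if L.size < 3:
        return None
    try:
        return sma_fit(
            L, d, log_transform=log_transform, x_label="distance_from_top", y_label="D_H"
        )
    except ValueError:
        return None
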