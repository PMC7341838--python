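"""Power-law fitting of the time-dependent axial diffusivity and the
associated statistical tests.

The central model is the short-range-disorder power law

    D(t) ~= D_inf + c * t^(-1/2),

fit by ordinary least squares of D against 1/sqrt(t) (the dynamical
exponent is held at 1/2; a diagnostic free-exponent fit exists but plays no
role in inference).  For highly dispersed fiber bundles the transverse
diffusivity of tilted axons leaks a 1/t term into the axial projection, so
a two-regressor variant adds c' / t.  Ensemble parameters are
volume-weighted means of the per-axon fits.  The significance of the time
dependence is a one-sided test of a positive slope of D versus 1/sqrt(t);
paired parameter comparisons use the one-sided Wilcoxon signed-rank test.
Also provides the relative diffusivity reduction zeta = (D0 - D_inf)/D_inf
and its regression against the squared coefficient of variation of radius,
the quadratic caliber signature zeta ~ CV^2(r).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "PowerLawFit",
    "ZetaResult",
    "WilcoxonResult",
    "fit_power_law",
    "fit_power_law_corrected",
    "fit_power_law_free",
    "ensemble_params",
    "dispersion_scaling",
    "zeta_relation",
    "mixture_D0",
    "wilcoxon_one_sided",
    "slope_correlation_test",
    "UNIFORM_THETA_DEG",
]

UNIFORM_THETA_DEG = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))


@dataclass
class PowerLawFit:
    """Result of fitting D(t) = D_inf + c / sqrt(t) [+ c' / t]."""

    D_inf: float
    c: float
    D_inf_se: float
    c_se: float
    p_value: float  # one-sided, H1: c > 0
    window: tuple[float, float]
    c_prime: float | None = None
    c_prime_se: float | None = None
    theta: float = 0.5  # fixed dynamical exponent


@dataclass
class ZetaResult:
    """Per-axon relative diffusivity reduction and its CV^2(r) regression."""

    zeta: np.ndarray
    D0: float
    slope: float
    intercept: float
    pearson_r: float


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float
    n_used: int
    n_zeros_dropped: int


def _window_mask(t: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(t.size, dtype=bool)
    lo, hi = window
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients, standard errors and residual dof."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.zeros(X.shape[1])
    return beta, se, dof


def _one_sided_p(stat: float, dof: int) -> float:
    if dof <= 0:
        return float("nan")
    return float(stats.t.sf(stat, dof))


def fit_power_law(
    t: np.ndarray,
    D: np.ndarray,
    window: tuple[float, float] | None = (20.0, 80.0),
) -> PowerLawFit:
    """OLS fit of D against 1/sqrt(t) over the window (default 20-80 ms).

    Returns intercept D_inf, slope c with their standard errors, and the
    one-sided p-value testing positive slope (restrictions present)
    against the null of no positive time dependence.

    ``D`` may be 2d with one row per replicate (e.g. independent seeds):
    the mean curve is fit and the standard errors are taken from the
    replicate spread of per-replicate fits instead of the OLS covariance.
    """
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        fits = [fit_power_law(t, row, window=window) for row in D]
        mean_fit = fit_power_law(t, D.mean(axis=0), window=window)
        n_rep = D.shape[0]
        d_se = float(np.std([f.D_inf for f in fits], ddof=1) / math.sqrt(n_rep))
        c_se = float(np.std([f.c for f in fits], ddof=1) / math.sqrt(n_rep))
        p = _one_sided_p(mean_fit.c / c_se if c_se > 0 else np.inf, n_rep - 1)
        return PowerLawFit(
            D_inf=mean_fit.D_inf, c=mean_fit.c, D_inf_se=d_se, c_se=c_se,
            p_value=p, window=mean_fit.window,
        )
    m = _window_mask(t, window)
    tw, Dw = t[m], D[m]
    if tw.size < 3:
        raise ValueError("need at least 3 points in the fit window")
    if np.unique(tw).size < tw.size:
        raise ValueError("duplicated diffusion times in the fit window")
    X = np.column_stack([np.ones(tw.size), 1.0 / np.sqrt(tw)])
    beta, se, dof = _ols(X, Dw)
    p = _one_sided_p(beta[1] / se[1] if se[1] > 0 else np.inf, dof)
    win = (float(tw.min()), float(tw.max()))
    return PowerLawFit(
        D_inf=float(beta[0]), c=float(beta[1]),
        D_inf_se=float(se[0]), c_se=float(se[1]),
        p_value=p, window=win,
    )


def fit_power_law_corrected(
    t: np.ndarray,
    D: np.ndarray,
    window: tuple[float, float] | None = (20.0, 80.0),
) -> PowerLawFit:
    """Two-regressor fit D = D_inf + c/sqrt(t) + c'/t for dispersed bundles
    where the transverse 1/t tail of tilted axons leaks into the axial
    projection."""
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    m = _window_mask(t, window)
    tw, Dw = t[m], D[m]
    if tw.size < 4:
        raise ValueError("need at least 4 points for the corrected fit")
    X = np.column_stack([np.ones(tw.size), 1.0 / np.sqrt(tw), 1.0 / tw])
    if np.linalg.cond(X) > 1e8:
        warnings.warn("1/sqrt(t) and 1/t regressors nearly collinear over this window",
                      stacklevel=2)
    beta, se, dof = _ols(X, Dw)
    p = _one_sided_p(beta[1] / se[1] if se[1] > 0 else np.inf, dof)
    win = (float(tw.min()), float(tw.max()))
    return PowerLawFit(
        D_inf=float(beta[0]), c=float(beta[1]),
        D_inf_se=float(se[0]), c_se=float(se[1]),
        p_value=p, window=win,
        c_prime=float(beta[2]), c_prime_se=float(se[2]),
    )


def fit_power_law_free(
    t: np.ndarray, D: np.ndarray, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Diagnostic nonlinear fit D = D_inf + c * t^(-theta) with the exponent
    free; returns (D_inf, c, theta).  Not used for inference."""
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    m = _window_mask(t, window)
    start = fit_power_law(t[m], D[m], window=None)
    popt, _ = curve_fit(
        lambda tt, d, c, th: d + c * tt ** (-th),
        t[m], D[m], p0=[start.D_inf, max(start.c, 1e-6), 0.5], maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def ensemble_params(fits: list[PowerLawFit], fractions: np.ndarray) -> tuple[float, float]:
    """Volume-weighted ensemble (D_inf, c) = (<D_i,inf>, <c_i>)."""
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("volume fractions must sum to 1")
    D_inf = float(f @ np.array([x.D_inf for x in fits]))
    c = float(f @ np.array([x.c for x in fits]))
    return D_inf, c


def dispersion_scaling(value_at_0: float, theta_deg: float) -> float:
    """Predicted axial quantity of a dispersed bundle: value * cos^2(theta),
    with theta the aggregate polar dispersion angle (so cos^2 theta equals
    the orientation average <cos^2>)."""
    if not 0.0 <= theta_deg <= UNIFORM_THETA_DEG + 1e-9:
        raise ValueError(f"theta must lie in [0, {UNIFORM_THETA_DEG:.2f}] degrees")
    return value_at_0 * math.cos(math.radians(theta_deg)) ** 2


def mixture_D0(D_a: float, D_m: float, f_m: float) -> float:
    """Volume-weighted intrinsic diffusivity (1 - f_m) D_a + f_m D_m."""
    if not 0.0 <= f_m <= 1.0:
        raise ValueError("f_m must be in [0, 1]")
    return (1.0 - f_m) * D_a + f_m * D_m


def zeta_relation(
    D0: float, D_inf: np.ndarray, cv: np.ndarray
) -> ZetaResult:
    """zeta_i = (D0 - D_i,inf)/D_i,inf regressed against CV^2(r)."""
    D_inf = np.asarray(D_inf, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if np.any(D_inf <= 0):
        raise ValueError("bulk diffusivities must be positive")
    zeta = D0 / D_inf - 1.0
    cv2 = cv**2
    if np.ptp(cv2) == 0:
        raise ValueError("degenerate CV spread; regression undefined")
    res = stats.linregress(cv2, zeta)
    return ZetaResult(
        zeta=zeta, D0=D0,
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
    )


def wilcoxon_one_sided(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater"
) -> WilcoxonResult:
    """One-sided paired Wilcoxon signed-rank test of a vs b.

    Exact null distribution for n <= 15 pairs, normal approximation beyond;
    zero differences are dropped (their count is reported).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need matching non-empty paired samples")
    d = a - b
    nz = d != 0
    n_dropped = int((~nz).sum())
    d = d[nz]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if d.size <= 15 else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return WilcoxonResult(
        p_value=float(res.pvalue), statistic=float(res.statistic),
        n_used=int(d.size), n_zeros_dropped=n_dropped,
    )


def slope_correlation_test(t: np.ndarray, D: np.ndarray) -> float:
    """One-sided p-value for a positive slope of D versus 1/sqrt(t)
    (null: no positive time dependence), from the regression t-statistic."""
    fit = fit_power_law(t, D, window=None)
    return fit.p_value
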