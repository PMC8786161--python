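"""Trajectory analysis: per-epoch peaks, orbit classification, Lyapunov
estimates, power-law tail MLE and power/exponential curve fits.

The quantitative pipeline mirrors how the perturbation-response experiments
are evaluated: for every perturbation epoch the transient is discarded and
the peak of the summed matrix observable M is recorded; the collection of
per-epoch peaks is then (a) regressed against the perturbation magnitude
with power / exponential curve fits compared by MSE-based information
criteria, and (b) fed to a maximum-likelihood power-law tail fit with the
lower cutoff selected by the Kolmogorov-Smirnov distance (Clauset-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, special

__all__ = [
    "EpochSummary",
    "PowerLawFit",
    "CurveFit",
    "OrbitClassification",
    "remove_transient",
    "epoch_peaks",
    "classify_orbit",
    "lyapunov_local",
    "powerlaw_mle",
    "fit_curve",
    "information_criteria",
    "detect_changepoint",
]


# --------------------------------------------------------------------------
# per-epoch summaries


@dataclass
class EpochSummary:
    """Post-transient summary of one perturbation epoch."""

    epoch: int
    eps: np.ndarray
    eps_sum: float
    max_M: float
    max_F: float
    orbit_period: int | None   # None when undetermined, 0 when aperiodic
    stable: bool


def remove_transient(series: np.ndarray, fraction: float = 0.25,
                     steps: int | None = None) -> np.ndarray:
    """Drop the leading transient of an epoch series.

    Either a fixed number of leading samples (``steps``) or a fraction of
    the length (default 25%).  An empty result signals an over-trimmed
    (unusable) epoch via ValueError.
    """
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty series")
    cut = int(steps) if steps is not None else int(np.floor(fraction * len(series)))
    if cut >= len(series):
        raise ValueError("transient removal leaves an empty epoch")
    return series[cut:]


@dataclass
class OrbitClassification:
    """Result of peak-level orbit classification.

    ``period`` counts distinct alternating peak levels (1 = simple limit
    cycle, 2 = period-doubled two-orbit, ...); ``aperiodic`` marks peak
    trains whose levels do not repeat periodically.
    """

    period: int | None
    aperiodic: bool
    n_peaks: int


class UndeterminedOrbitError(ValueError):
    """Too few local maxima to classify the orbit."""


def classify_orbit(series: np.ndarray, rel_tol: float = 0.01,
                   max_peaks: int = 12) -> OrbitClassification:
    """Classify a post-transient oscillation by its distinct peak levels.

    Local maxima are located, the last ``max_peaks`` of them are clustered
    by height with relative tolerance ``rel_tol`` (of the peak amplitude),
    and the cluster-label sequence is checked for periodicity.  Returns the
    number of alternating levels, or flags the train aperiodic.
    """
    series = np.asarray(series, dtype=float)
    pk, _ = signal.find_peaks(series)
    if len(pk) < 4:
        raise UndeterminedOrbitError(
            f"need >= 4 local maxima to classify, found {len(pk)}")
    heights = series[pk][-max_peaks:]
    scale = float(np.max(np.abs(heights)))
    tol = rel_tol * (scale if scale > 0 else 1.0)

    # cluster by sorting and splitting at gaps larger than the tolerance
    order = np.argsort(heights)
    labels = np.empty(len(heights), dtype=int)
    lab = 0
    labels[order[0]] = 0
    for a, b in zip(order[:-1], order[1:]):
        if heights[b] - heights[a] > tol:
            lab += 1
        labels[b] = lab
    n_levels = lab + 1

    if n_levels > len(heights) // 2:
        return OrbitClassification(period=0, aperiodic=True, n_peaks=len(pk))
    # periodicity of the label sequence with period = n_levels
    seq = labels
    periodic = all(
        seq[i] == seq[i % n_levels] for i in range(len(seq))
    )
    if not periodic:
        return OrbitClassification(period=0, aperiodic=True, n_peaks=len(pk))
    return OrbitClassification(period=n_levels, aperiodic=False, n_peaks=len(pk))


def epoch_peaks(traj, transient_fraction: float = 0.25,
                classify: bool = True) -> list[EpochSummary]:
    """One :class:`EpochSummary` per epoch of a Trajectory.

    Peaks are maxima of the recorded M (and F) samples after transient
    removal.  An epoch is stable when its post-transient peak train
    classifies as periodic; epochs with an empty post-transient window or a
    divergence are flagged unstable (maxima reported as NaN for empty
    windows).
    """
    out: list[EpochSummary] = []
    for e in range(traj.n_epochs):
        idx = traj.epoch_indices(e)
        eps = traj.eps[e]
        eps_sum = float(traj.eps_sum[e])
        diverged_here = traj.diverged and traj.diverged_epoch == e
        if len(idx) == 0:
            out.append(EpochSummary(e, eps, eps_sum, np.nan, np.nan, None, False))
            continue
        M = traj.M[idx]
        F = traj.F[idx]
        try:
            Mt = remove_transient(M, fraction=transient_fraction)
            Ft = remove_transient(F, fraction=transient_fraction)
        except ValueError:
            out.append(EpochSummary(e, eps, eps_sum, np.nan, np.nan, None, False))
            continue
        max_M = float(np.max(Mt))
        max_F = float(np.max(Ft))
        period: int | None = None
        stable = bool(np.all(np.isfinite(Mt))) and not diverged_here
        if classify and stable:
            try:
                oc = classify_orbit(Mt)
                period = oc.period
                stable = not oc.aperiodic
            except UndeterminedOrbitError:
                period = None
        out.append(EpochSummary(e, eps, eps_sum, max_M, max_F, period, stable))
    return out


def summaries_frame(summaries: list[EpochSummary]):
    """Epoch summaries as a tidy pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "epoch": [s.epoch for s in summaries],
        "eps_sum": [s.eps_sum for s in summaries],
        "max_M": [s.max_M for s in summaries],
        "max_F": [s.max_F for s in summaries],
        "orbit_period": [s.orbit_period for s in summaries],
        "stable": [s.stable for s in summaries],
    })


# --------------------------------------------------------------------------
# Lyapunov estimation


def lyapunov_local(deriv, y0, dt: float, n_steps: int, window: int = 200,
                   d0: float = 1e-7, method: str = "rk4"):
    """Window-resolved estimates of the largest Lyapunov exponent.

    Propagates a tangent vector alongside the trajectory (directional
    derivative of ``deriv`` by central differences) and renormalises it
    every ``window`` steps; each window yields one local exponent
    ln(growth)/(window*dt).  Returns (times, local_exponents).  A trajectory
    that has collapsed to a fixed point yields non-positive estimates and a
    warning.
    """
    from .integrate import step

    y = np.asarray(y0, dtype=float).copy()
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(y.shape)
    v /= np.linalg.norm(v)

    def aug_deriv(t, z):
        yy = z[: y.size].reshape(y.shape)
        vv = z[y.size:].reshape(y.shape)
        f0 = np.asarray(deriv(t, yy), dtype=float)
        # directional derivative J(y) @ v by central differences; the step
        # scales with the state so it is not absorbed for large |y|
        h = d0 * (1.0 + np.linalg.norm(yy))
        fp = np.asarray(deriv(t, yy + h * vv), dtype=float)
        fm = np.asarray(deriv(t, yy - h * vv), dtype=float)
        return np.concatenate([f0.ravel(), ((fp - fm) / (2 * h)).ravel()])

    exponents = []
    times = []
    z = np.concatenate([y.ravel(), v.ravel()])
    t = 0.0
    n_windows = n_steps // window
    for k in range(n_windows):
        for _ in range(window):
            z = step(aug_deriv, z, t, dt, method)
            t += dt
        vv = z[y.size:]
        g = np.linalg.norm(vv)
        exponents.append(np.log(g) / (window * dt))
        times.append(t)
        z[y.size:] = vv / g
    exponents = np.asarray(exponents)
    if len(exponents) and np.all(exponents <= 0):
        warnings.warn("trajectory appears non-chaotic (all local exponents <= 0)")
    return np.asarray(times), exponents


# --------------------------------------------------------------------------
# power-law tail MLE (Clauset-style)


@dataclass
class PowerLawFit:
    """Maximum-likelihood power-law tail fit with KS-selected cutoff.

    ``alpha`` is the (positive) tail exponent of p(x) ~ x^-alpha above
    ``x_min``; ``ccdf_slope`` = -(alpha - 1) is the signed slope of the
    fitted tail survival function on log-log axes (reported separately
    because figure captions mix the two conventions).
    """

    alpha: float
    x_min: float
    ks_distance: float
    log_likelihood: float
    n_tail: int

    @property
    def ccdf_slope(self) -> float:
        return -(self.alpha - 1.0)


def _continuous_ks(tail: np.ndarray, alpha: float, x_min: float) -> float:
    x = np.sort(tail)
    n = len(x)
    model = 1.0 - (x / x_min) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(ecdf_hi - model), np.abs(ecdf_lo - model))))


def powerlaw_mle(samples, discrete: bool = False,
                 x_min_candidates=None, min_tail_frac: float = 0.0) -> PowerLawFit:
    """Power-law tail fit by maximum likelihood with KS cutoff selection.

    For every candidate lower cutoff taken from the observed values, the
    scaling exponent is fitted by maximum likelihood -- continuous form
    alpha = 1 + n / sum ln(x_i/x_min), or discrete form by numerical
    maximisation of L(alpha) = -n ln zeta(alpha, x_min) - alpha sum ln x_i
    (Hurwitz zeta) -- and the Kolmogorov-Smirnov distance between the
    empirical and fitted tail CDFs is evaluated; the fit minimising the KS
    distance is returned.  ``min_tail_frac`` restricts the scan to cutoffs
    that keep at least that fraction of the sample in the tail (guards
    against overfitting a tiny upper tail of a non-power-law sample).
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 positive samples")
    if np.any(x <= 0):
        raise ValueError("power-law samples must be positive")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: all values equal")

    xs = np.unique(x)
    if x_min_candidates is None:
        x_min_candidates = xs[:-1]  # need at least 2 tail points
    best: PowerLawFit | None = None
    n_min = max(2, int(np.ceil(min_tail_frac * len(x))))
    for xm in np.asarray(x_min_candidates, dtype=float):
        tail = x[x >= xm]
        n = len(tail)
        if n < n_min:
            continue
        logs = np.log(tail / xm)
        s = logs.sum()
        if s <= 0:
            continue
        if not discrete:
            alpha = 1.0 + n / s
            ll = n * np.log((alpha - 1.0) / xm) - alpha * s
        else:
            slogx = np.log(tail).sum()

            def nll(a):
                return n * np.log(special.zeta(a, xm)) + a * slogx

            res = optimize.minimize_scalar(nll, bounds=(1.01, 20.0),
                                           method="bounded")
            alpha = float(res.x)
            ll = -float(res.fun)
        ks = _continuous_ks(tail, alpha, xm)
        fit = PowerLawFit(alpha=float(alpha), x_min=float(xm),
                          ks_distance=ks, log_likelihood=float(ll), n_tail=n)
        if best is None or ks < best.ks_distance:
            best = fit
    if best is None:
        raise ValueError("no valid x_min candidate (tails too short)")
    return best


# --------------------------------------------------------------------------
# curve fits and information criteria


@dataclass
class CurveFit:
    """Least-squares fit of y = a*x^b (power) or y = a*e^(b*x) (exponential)."""

    form: str
    a: float
    b: float
    mse: float
    aic: float
    bic: float
    n: int
    k: int = 2

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "power":
            return self.a * x ** self.b
        return self.a * np.exp(self.b * x)


def information_criteria(mse: float, n: int, k: int,
                         convention: str = "printed") -> tuple[float, float]:
    """AIC/BIC from the mean squared error.

    The default "printed" convention is aic = -n ln(mse) + 2k and
    bic = -n ln(mse) + k ln(n); the "conventional" textbook form flips the
    sign of the mse term (n ln(mse) + ...).  The two differ only in that
    sign, so smaller-is-better applies to the conventional form and
    model comparisons under the printed form compare like against like.
    """
    if mse <= 0:
        raise ValueError("mse must be > 0 (a perfect fit has undefined criteria)")
    if n <= k:
        raise ValueError("need n > k")
    term = n * np.log(mse)
    if convention == "printed":
        return float(-term + 2 * k), float(-term + k * np.log(n))
    if convention == "conventional":
        return float(term + 2 * k), float(term + k * np.log(n))
    raise ValueError(f"unknown convention {convention!r}")


def fit_curve(x, y, form: str = "power", refine: bool = True) -> CurveFit:
    """Fit a two-parameter power or exponential curve.

    Seeds the coefficients by linear regression on the appropriate log
    scale, then (``refine=True``) polishes by nonlinear least squares on the
    original scale.  With ``refine=False`` the log-scale regression is kept:
    on per-epoch peak data whose scatter spans decades the original-scale
    polish is dominated by the largest peaks, whereas the log-log regression
    is what the perturbation-response plots display.  MSE is evaluated on
    the original scale either way and AIC/BIC follow the printed convention
    of :func:`information_criteria`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if form not in ("power", "exponential"):
        raise ValueError(f"unknown form {form!r}")
    if form == "power" and np.any(x <= 0):
        raise ValueError("power fit requires strictly positive x")
    if len(x) < 3:
        raise ValueError("need at least 3 points")

    if np.all(y > 0):
        ly = np.log(y)
        if form == "power":
            b0, la0 = np.polyfit(np.log(x), ly, 1)
        else:
            b0, la0 = np.polyfit(x, ly, 1)
        a0 = float(np.exp(la0))
        b0 = float(b0)
    else:  # log-transform unavailable: direct nonlinear fit from a flat seed
        a0, b0 = float(np.mean(y)), 0.0

    def model(xx, a, b):
        return a * xx ** b if form == "power" else a * np.exp(b * xx)

    a, b = a0, b0
    if refine:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(model, x, y, p0=[a0, b0], maxfev=20000)
            a, b = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass
    resid = y - model(x, a, b)
    mse = float(np.mean(resid ** 2))
    if mse > 0:
        aic, bic = information_criteria(mse, len(x), 2)
    else:
        aic = bic = float("nan")
    return CurveFit(form=form, a=a, b=b, mse=mse, aic=aic, bic=bic, n=len(x))


def detect_changepoint(x, y, min_frac: float = 0.15):
    """Split point of a two-regime (x, y) relation on log-log axes.

    Scans candidate splits (quantiles of x keeping at least ``min_frac`` of
    the points on each side), fits a straight line to log y vs log x on each
    side and returns the split value of x minimising the total squared
    residual.  Used to separate the power-law domain of the perturbation
    response from the non-power-law domain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    order = np.argsort(x)
    lx, ly = np.log(x[order]), np.log(y[order])
    n = len(lx)
    lo = max(3, int(min_frac * n))
    best_sse = np.inf
    best_split = None
    for i in range(lo, n - lo):
        sse = 0.0
        for seg in (slice(0, i), slice(i, n)):
            c = np.polyfit(lx[seg], ly[seg], 1)
            r = ly[seg] - np.polyval(c, lx[seg])
            sse += float(r @ r)
        if sse < best_sse:
            best_sse = sse
            best_split = i
    if best_split is None:
        raise ValueError("too few points for changepoint detection")
    return float(np.exp(0.5 * (lx[best_split - 1] + lx[best_split])))
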