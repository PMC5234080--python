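"""Single-particle-tracking analysis: MSD fitting, motion classification,
pause detection, diffusion-histogram mixture fitting, dwell-time and FRAP
exponential fits, and a binomial colocalization statistic.

These routines operate on trajectory tables (per-frame positions) and
intensity time series, whether produced by the simulator or supplied
externally.  For 2D Brownian motion the mean square displacement grows as
``MSD(t) = 4 D t``; anomalous transport is classified through the exponent
``alpha`` of a power-law fit (``alpha ~ 1`` Brownian, ``alpha ~ 2``
directed, ``alpha < 1`` confined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "MixtureFit",
    "ExpFit",
    "compute_msd",
    "fit_msd",
    "detect_pauses",
    "fit_diffusion_mixture",
    "fit_dwell_exponential",
    "fit_frap_recovery",
    "frap_diffusion",
    "background_subtract",
    "colocalization_binomial",
]


@dataclass
class MSDCurve:
    """Time-averaged mean square displacement of one trajectory."""

    lags: np.ndarray  # lag times, s
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs per lag


@dataclass
class DiffusionFit:
    """Result of fitting an MSD curve.

    ``classification`` is one of ``brownian``, ``directed``, ``confined`` or
    ``rejected`` (poor fit or negative intercept under the quality filter).
    """

    D: float  # um^2 s^-1
    alpha: float  # anomalous exponent (1.0 for the linear model)
    intercept: float  # um^2
    r_squared: float
    classification: str
    model: str


@dataclass
class MixtureFit:
    """Maximum-likelihood 1D Gaussian mixture fit."""

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    log_likelihood: float
    ll_history: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class ExpFit:
    """Exponential lifetime fit with a 95% confidence interval."""

    lifetime: float  # s
    ci_low: float
    ci_high: float
    residual: float = math.nan


def compute_msd(positions: np.ndarray, max_lag: int) -> MSDCurve:
    """Time-averaged MSD over all start points, for lags 1..max_lag frames.

    ``positions`` is (n, 2) with one row per frame at uniform frame spacing;
    lag times are returned in frame units scaled by the caller via
    :func:`msd_lag_times` or by passing frame interval to the fit.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need at least two positions")
    n = pos.shape[0]
    if not (1 <= max_lag < n):
        raise ValueError("max_lag must satisfy 1 <= max_lag < trajectory length")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for i, k in enumerate(lags):
        d = pos[k:] - pos[:-k]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        n_pairs[i] = n - k
    return MSDCurve(lags=lags.astype(float), msd=msd, n_pairs=n_pairs)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_msd(
    curve: MSDCurve,
    model: str = "linear",
    frame_interval: float = 1.0,
    r2_min: float = 0.95,
    require_positive_intercept: bool = True,
    alpha_brownian: tuple[float, float] = (0.8, 1.2),
    alpha_directed: float = 1.6,
) -> DiffusionFit:
    """Fit an MSD curve and classify the motion.

    ``linear`` fits ``MSD = 4 D t + b`` by least squares; trajectories with
    ``R^2 <= r2_min`` or (optionally) a negative intercept are marked
    ``rejected`` — the quality filter used to exclude non-diffusive spots.
    ``power`` fits ``MSD = 4 D t^alpha`` (log-log least squares) and
    classifies by ``alpha``: Brownian within ``alpha_brownian``, directed
    above ``alpha_directed``, confined below the Brownian band.
    """
    t = np.asarray(curve.lags, dtype=float) * frame_interval
    y = np.asarray(curve.msd, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 lags to fit")
    if np.ptp(t) == 0:
        raise ValueError("degenerate lag values")

    if model == "linear":
        slope, intercept = np.polyfit(t, y, 1)
        yhat = slope * t + intercept
        r2 = _r_squared(y, yhat)
        D = max(slope / 4.0, 0.0)
        intercept_floor = -1e-9 * max(float(np.max(np.abs(y))), 1e-300)
        if r2 <= r2_min or (require_positive_intercept and intercept < intercept_floor):
            cls = "rejected"
        else:
            cls = "brownian"
        return DiffusionFit(
            D=D, alpha=1.0, intercept=float(intercept), r_squared=r2,
            classification=cls, model="linear",
        )
    if model == "power":
        if np.any(y <= 0):
            raise ValueError("power-law fit requires positive MSD values")
        b, loga = np.polyfit(np.log(t), np.log(y / 4.0), 1)
        alpha = float(b)
        D = float(np.exp(loga))
        yhat = 4.0 * D * t**alpha
        r2 = _r_squared(y, yhat)
        if r2 <= r2_min:
            cls = "rejected"
        elif alpha_brownian[0] <= alpha <= alpha_brownian[1]:
            cls = "brownian"
        elif alpha >= alpha_directed:
            cls = "directed"
        elif alpha < alpha_brownian[0]:
            cls = "confined"
        else:
            cls = "brownian"  # between bands: closest archetype is Brownian
        return DiffusionFit(
            D=D, alpha=alpha, intercept=0.0, r_squared=r2,
            classification=cls, model="power",
        )
    raise ValueError("model must be 'linear' or 'power'")


def default_max_lag(n_frames: int) -> int:
    """Quarter of the trajectory length, at least 2 lags."""
    return max(2, n_frames // 4)


def detect_pauses(
    positions: np.ndarray,
    frame_interval: float,
    window: float = 1.0,
    sd_threshold: float = 0.05,
) -> list[tuple[float, float]]:
    """Detect pauses: spans longer than ``window`` with positional s.d. below
    ``sd_threshold``.

    The positional s.d. of a span is ``sqrt(var(x) + var(y))`` about the
    span mean.  Every window of ``window / frame_interval`` frames is
    tested; overlapping qualifying windows are merged and merged spans not
    longer than ``window`` are discarded.  Returns (start_s, end_s) pairs.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    w = int(round(window / frame_interval))
    if w < 2 or n <= w:
        return []
    # Rolling variance via cumulative sums.
    c1 = np.vstack([np.zeros(2), np.cumsum(pos, axis=0)])
    c2 = np.vstack([np.zeros(2), np.cumsum(pos**2, axis=0)])
    # window of w+1 frames spans time w * frame_interval
    k = w + 1
    s1 = c1[k:] - c1[:-k]
    s2 = c2[k:] - c2[:-k]
    var = s2 / k - (s1 / k) ** 2
    sd = np.sqrt(np.clip(var.sum(axis=1), 0.0, None))
    quiet = sd < sd_threshold  # window starting at frame i covers [i, i+w]
    covered = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(quiet):
        covered[i: i + k] = True
    pauses = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            if (j - i) * frame_interval > window:
                pauses.append((i * frame_interval, j * frame_interval))
            i = j + 1
        else:
            i += 1
    return pauses


_SIGMA_FLOOR = 1e-9


def fit_diffusion_mixture(
    values,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MixtureFit:
    """Fit a k-component 1D Gaussian mixture by maximum likelihood (EM).

    The fit runs on the raw values, not a binned histogram.  Initialisation
    is deterministic: component means at the k evenly spaced sample
    quantiles, equal weights, and a shared initial width from the sample
    s.d., so repeated fits of the same data agree exactly.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if k <= 0:
        raise ValueError("k must be >= 1")
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}")

    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q)
    sigma0 = max(x.std(), _SIGMA_FLOOR)
    sigmas = np.full(k, sigma0 / max(k, 1))
    weights = np.full(k, 1.0 / k)

    ll_history = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        # E step (log-space responsibilities)
        logp = (
            np.log(np.maximum(weights, 1e-300))[:, None]
            + stats.norm.logpdf(x[None, :], means[:, None],
                                np.maximum(sigmas, _SIGMA_FLOOR)[:, None])
        )
        lse = special.logsumexp(logp, axis=0)
        ll = float(lse.sum())
        ll_history.append(ll)
        resp = np.exp(logp - lse[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - means**2
        sigmas = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll

    order = np.argsort(means)
    weights = weights[order] / weights.sum()
    return MixtureFit(
        weights=weights,
        means=means[order],
        sigmas=sigmas[order],
        log_likelihood=ll_history[-1],
        ll_history=np.asarray(ll_history),
        n_iter=len(ll_history),
        converged=converged,
    )


def fit_dwell_exponential(dwells, conf: float = 0.95) -> ExpFit:
    """Exponential mean-lifetime fit of dwell times with a profile-likelihood CI.

    The MLE of the mean is the sample mean; the confidence interval is the
    set of means not rejected by the likelihood-ratio test at level
    ``conf`` (chi-squared with one degree of freedom).
    """
    x = np.asarray(dwells, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 dwell times")
    if np.any(x <= 0):
        raise ValueError("dwell times must be positive")
    n = x.size
    mu_hat = float(x.mean())

    def negll(mu):
        return n * math.log(mu) + n * mu_hat / mu

    target = negll(mu_hat) + 0.5 * stats.chi2.ppf(conf, df=1)

    def g(mu):
        return negll(mu) - target

    lo = optimize.brentq(g, mu_hat * 1e-3, mu_hat)
    hi = optimize.brentq(g, mu_hat, mu_hat * 1e3)
    return ExpFit(lifetime=mu_hat, ci_low=lo, ci_high=hi, residual=0.0)


def fit_frap_recovery(times, intensities, conf: float = 0.95) -> ExpFit:
    """Single-exponential recovery fit ``I(t) = I_inf (1 - exp(-t / tau))``.

    ``intensities`` should be normalised to the pre-bleach level (so
    ``I_inf`` is the mobile fraction).  The CI on the recovery lifetime is
    the large-sample normal interval from the least-squares covariance.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size == 0 or t.size != y.size:
        raise ValueError("times and intensities must be equal-length and nonempty")

    def model(t, i_inf, tau):
        return i_inf * -np.expm1(-t / tau)

    tau0 = max(t.max() / 3.0, 1e-6)
    popt, pcov = optimize.curve_fit(
        model, t, y, p0=[max(y.max(), 1e-6), tau0],
        bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000,
    )
    i_inf, tau = popt
    resid = float(np.sqrt(np.mean((y - model(t, *popt)) ** 2)))
    se = math.sqrt(max(pcov[1, 1], 0.0))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return ExpFit(
        lifetime=float(tau),
        ci_low=max(float(tau) - z * se, 0.0),
        ci_high=float(tau) + z * se,
        residual=resid,
    )


def frap_diffusion(lifetime: float, roi_radius: float) -> float:
    """Diffusion constant implied by a FRAP recovery lifetime.

    Uses the circular-spot half-time relation ``D = 0.224 r^2 / t_half``
    with ``t_half = lifetime * ln 2`` for a single-exponential recovery.
    """
    if lifetime <= 0 or roi_radius <= 0:
        raise ValueError("lifetime and roi_radius must be positive")
    t_half = lifetime * math.log(2.0)
    return 0.224 * roi_radius**2 / t_half


def background_subtract(trace, background_trace):
    """Subtract a nearby dark-region trace from a spot intensity trace."""
    a = np.asarray(trace, dtype=float)
    b = np.asarray(background_trace, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trace and background must have the same length")
    return a - b


def colocalization_binomial(n_spots: int, n_within: int, area_fraction: float) -> float:
    """Upper-tail binomial probability that >= ``n_within`` of ``n_spots``
    random spots land in a region covering ``area_fraction`` of the cell.

    Computed in log space, so vanishingly small tails (e.g. < 1e-70) are
    returned accurately.
    """
    if not (0 < area_fraction < 1):
        raise ValueError("area_fraction must be in (0, 1)")
    if not (0 <= n_within <= n_spots):
        raise ValueError("need 0 <= n_within <= n_spots")
    if n_within == 0:
        return 1.0
    # P(X >= k) = sf(k - 1)
    logp = stats.binom.logsf(n_within - 1, n_spots, area_fraction)
    return float(np.exp(logp))


def log10_colocalization_binomial(n_spots: int, n_within: int, area_fraction: float) -> float:
    """log10 of :func:`colocalization_binomial`, safe for extreme tails."""
    if n_within == 0:
        return 0.0
    if not (0 < area_fraction < 1):
        raise ValueError("area_fraction must be in (0, 1)")
    logp = stats.binom.logsf(n_within - 1, n_spots, area_fraction)
    return float(logp / math.log(10.0))
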