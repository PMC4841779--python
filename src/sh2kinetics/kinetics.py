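"""Apparent membrane binding kinetics from single-molecule trajectories.

gamma_on(t): newly appearing membrane-bound molecules per unit time, counted
in sliding windows (default 0.8 min).  lambda_off: effective dissociation
rate from the dwell-time distribution — censored maximum likelihood with an
additive photobleaching correction.  Recovery time constants tau come from
nonlinear least squares of the first-order recovery model A*(1 - exp(-t/tau)).

Because track lengths are quantized to whole frames and exponential dwells
are memoryless, the number of frames a molecule is observed is exactly
geometric with survival q = exp(-lambda * dt); `estimate_lambda_off`
maximizes that geometric likelihood (the continuous-time exponential MLE is
its fine-frame limit and is exposed separately for real-valued dwell data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from sh2kinetics.locfit import track_summary

#: The standard counting window: 0.8 min of acquisition.
DEFAULT_WINDOW_S = 48.0

#: Recovery fits with R^2 below this carry the poor-fit flag.
POOR_FIT_R2 = 0.5


# ----------------------------------------------------------------------
# gamma_on
# ----------------------------------------------------------------------

def estimate_gamma_on(
    trajectories: pd.DataFrame,
    frame_interval: float,
    window_length: float = DEFAULT_WINDOW_S,
    t_grid: np.ndarray | None = None,
    total_time: float | None = None,
) -> pd.DataFrame:
    """Windowed apparent on-rate from track start times.

    gamma_on for a window is the number of trajectories whose first frame
    falls inside the window, divided by the window length, reported in
    events/min.  Tracks present in frame 0 are pre-existing binding, not
    recruitment events, and are never counted.  ``t_grid`` gives the window
    start times (s); by default contiguous windows tile the acquisition.

    Returns a DataFrame: window_start_s, n_events, gamma_on_per_min,
    se_per_min (Poisson counting error).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if len(trajectories):
        starts = trajectories.groupby("track_id")["frame"].min().to_numpy()
        starts = starts[starts > 0] * frame_interval
        t_max = float(trajectories["frame"].max() + 1) * frame_interval
    else:
        starts = np.array([])
        t_max = 0.0
    if total_time is not None:
        t_max = total_time
    if t_grid is None:
        if t_max <= 0:
            raise ValueError("empty window grid: no data and no total_time given")
        t_grid = np.arange(0.0, t_max, window_length)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) == 0:
        raise ValueError("empty window grid")

    counts = np.array(
        [np.sum((starts >= t0) & (starts < t0 + window_length)) for t0 in t_grid]
    )
    per_min = 60.0 / window_length
    return pd.DataFrame(
        {
            "window_start_s": t_grid,
            "n_events": counts,
            "gamma_on_per_min": counts * per_min,
            "se_per_min": np.sqrt(counts) * per_min,
        }
    )


def gamma_on_from_bind_times(
    bind_times_s: np.ndarray,
    window_length: float = DEFAULT_WINDOW_S,
    total_time: float | None = None,
) -> pd.DataFrame:
    """Windowed gamma_on directly from ground-truth bind times (s)."""
    bind_times_s = np.asarray(bind_times_s, dtype=float)
    t_max = total_time if total_time is not None else (
        bind_times_s.max() if len(bind_times_s) else 0.0
    )
    if t_max <= 0:
        raise ValueError("empty window grid")
    t_grid = np.arange(0.0, t_max, window_length)
    counts = np.array(
        [
            np.sum((bind_times_s >= t0) & (bind_times_s < t0 + window_length))
            for t0 in t_grid
        ]
    )
    per_min = 60.0 / window_length
    return pd.DataFrame(
        {
            "window_start_s": t_grid,
            "n_events": counts,
            "gamma_on_per_min": counts * per_min,
            "se_per_min": np.sqrt(counts) * per_min,
        }
    )


# ----------------------------------------------------------------------
# lambda_off
# ----------------------------------------------------------------------

@dataclass
class LambdaOffResult:
    """Apparent off-rate estimate with provenance flags.

    lambda_off = lambda_observed - k_bleach.  ``degenerate`` marks fits where
    the observed rate does not exceed the bleach rate (the subtraction would
    be non-positive; no silent clipping is performed).  ``censored_dominated``
    marks data with no uncensored dwell at all, where only a lower bound on
    the dwell time (upper bound on lambda) is available.
    """

    lambda_off: float            # 1/s (nan when degenerate/censored_dominated)
    se: float                    # 1/s
    lambda_observed: float       # 1/s, before bleach correction
    k_bleach: float              # 1/s
    n_events: int
    n_censored: int
    degenerate: bool = False
    censored_dominated: bool = False


def _geometric_mle(
    lengths: np.ndarray, censored: np.ndarray, frame_interval: float
) -> tuple[float, float]:
    """MLE of lambda from frame-quantized dwells.

    Likelihood: uncensored K-frame tracks contribute (1-q) q^(K-1), censored
    ones q^K, with q = exp(-lambda dt).  qhat = S / (S + n_u) where S is the
    total number of survived frame transitions.
    """
    n_u = int(np.sum(~censored))
    S = float(np.sum(lengths[~censored] - 1) + np.sum(lengths[censored]))
    q = S / (S + n_u)
    if q <= 0.0:
        # every uncensored dwell lasted a single frame; lambda is large but
        # finite information-wise — report the single-frame bound
        q = 1.0 / (S + n_u + 1.0)
    lam = -np.log(q) / frame_interval
    # observed information in lambda (delta method through q)
    info = n_u * frame_interval**2 * q / (1.0 - q) ** 2
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return lam, se


def estimate_lambda_off(
    trajectories: pd.DataFrame,
    k_bleach: float,
    frame_interval: float,
    n_frames: int | None = None,
    exclude_first_frame: bool = True,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> LambdaOffResult:
    """Apparent off-rate from trajectory dwell times.

    Track lengths (frames) are treated as geometric observations of an
    exponential dwell; tracks reaching the final movie frame are
    right-censored; tracks already present in frame 0 are left-censored and
    excluded (``exclude_first_frame``).  The bleach rate (from config or an
    immobilized control) is subtracted additively.  ``n_bootstrap`` > 0
    replaces the observed-information standard error with a nonparametric
    bootstrap over trajectories.
    """
    if k_bleach < 0:
        raise ValueError("k_bleach must be non-negative")
    summary = track_summary(trajectories, n_frames=n_frames)
    if exclude_first_frame:
        summary = summary[summary["start_frame"] > 0]
    lengths = summary["length"].to_numpy()
    censored = summary["censored"].to_numpy()
    n = len(lengths)
    if n < 1:
        raise ValueError("no usable trajectories for lambda_off")

    if censored.all():
        # only a lower bound on dwell is available
        lam_upper = 1.0 / (np.mean(lengths) * frame_interval)
        return LambdaOffResult(
            lambda_off=np.nan, se=np.nan, lambda_observed=lam_upper,
            k_bleach=k_bleach, n_events=n, n_censored=int(censored.sum()),
            censored_dominated=True,
        )

    lam_obs, se = _geometric_mle(lengths, censored, frame_interval)
    if n_bootstrap > 0:
        rng = rng or np.random.default_rng(0)
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            reps[b], _ = _geometric_mle(lengths[idx], censored[idx], frame_interval)
        se = float(np.std(reps, ddof=1))

    if lam_obs <= k_bleach:
        return LambdaOffResult(
            lambda_off=np.nan, se=se, lambda_observed=lam_obs, k_bleach=k_bleach,
            n_events=n, n_censored=int(censored.sum()), degenerate=True,
        )
    return LambdaOffResult(
        lambda_off=lam_obs - k_bleach, se=se, lambda_observed=lam_obs,
        k_bleach=k_bleach, n_events=n, n_censored=int(censored.sum()),
    )


def fit_exponential_dwells(
    dwells_s: np.ndarray, censored: np.ndarray | None = None
) -> tuple[float, float]:
    """Continuous-time censored exponential MLE: lambda = n_unc / sum(t).

    Returns (lambda, standard error).  For real-valued dwell data (e.g.
    ground-truth simulator dwells)."""
    dwells_s = np.asarray(dwells_s, dtype=float)
    if censored is None:
        censored = np.zeros(len(dwells_s), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_u = int(np.sum(~censored))
    if n_u == 0:
        raise ValueError("all dwells censored; no uncensored information")
    total = float(dwells_s.sum())
    lam = n_u / total
    return lam, lam / np.sqrt(n_u)


def windowed_lambda_off(
    bind_times_s: np.ndarray,
    dwells_s: np.ndarray,
    censored: np.ndarray,
    window_length: float = DEFAULT_WINDOW_S,
    total_time: float | None = None,
    min_events: int = 30,
) -> pd.DataFrame:
    """lambda_off(t): censored exponential MLE over dwells grouped by the
    window their binding event starts in.  Windows with fewer than
    ``min_events`` dwells report NaN."""
    bind_times_s = np.asarray(bind_times_s, dtype=float)
    t_max = total_time if total_time is not None else bind_times_s.max()
    t_grid = np.arange(0.0, t_max, window_length)
    lam = np.full(len(t_grid), np.nan)
    se = np.full(len(t_grid), np.nan)
    for i, t0 in enumerate(t_grid):
        sel = (bind_times_s >= t0) & (bind_times_s < t0 + window_length)
        if sel.sum() >= min_events and (~censored[sel]).any():
            lam[i], se[i] = fit_exponential_dwells(dwells_s[sel], censored[sel])
    return pd.DataFrame(
        {"window_start_s": t_grid, "lambda_off_per_s": lam, "se_per_s": se}
    )


# ----------------------------------------------------------------------
# Recovery fitting
# ----------------------------------------------------------------------

@dataclass
class KineticFitResult:
    """First-order exponential recovery fit y = A*(1 - exp(-t/tau))."""

    tau: float                 # same unit as the supplied time axis
    tau_se: float
    amplitude: float
    r_squared: float
    poor_fit: bool             # R^2 < 0.5
    converged: bool
    model: str = "1-exp-recovery"


def fit_recovery(
    t: np.ndarray,
    y: np.ndarray,
    pin_amplitude: bool = False,
) -> KineticFitResult:
    """Fit the first-order recovery function A*(1 - exp(-t/tau)).

    ``t`` must be non-negative with >= 5 points; ``y`` is expected
    baseline-subtracted (and max-normalized if ``pin_amplitude``).  tau is
    initialized at time-to-half-max / ln 2 and bounded in (0, 10*t_max].
    The returned tau carries the time unit of ``t``.  Fits with R^2 < 0.5
    are flagged poor; non-convergence yields converged=False with NaN tau.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points for a recovery fit")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in recovery fit input")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")

    t_max = float(t.max())
    y_max = float(y.max())
    half_target = 0.5 * y_max
    above = np.flatnonzero(y >= half_target)
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else t_max / 4
    tau0 = min(max(t_half / np.log(2.0), 1e-9), 10 * t_max)

    def _fail() -> KineticFitResult:
        return KineticFitResult(
            tau=np.nan, tau_se=np.nan, amplitude=np.nan, r_squared=np.nan,
            poor_fit=True, converged=False,
        )

    try:
        if pin_amplitude:
            popt, pcov = curve_fit(
                lambda tt, tau: 1.0 - np.exp(-tt / tau),
                t, y, p0=[tau0], bounds=([1e-12], [10 * t_max]), maxfev=2000,
            )
            tau, amp = float(popt[0]), 1.0
            tau_var = pcov[0, 0]
        else:
            popt, pcov = curve_fit(
                lambda tt, a, tau: a * (1.0 - np.exp(-tt / tau)),
                t, y, p0=[max(y_max, 1e-12), tau0],
                bounds=([0.0, 1e-12], [np.inf, 10 * t_max]), maxfev=2000,
            )
            amp, tau = float(popt[0]), float(popt[1])
            tau_var = pcov[1, 1]
    except (RuntimeError, ValueError):
        return _fail()
    if not np.isfinite(tau):
        return _fail()

    fitted = amp * (1.0 - np.exp(-t / tau))
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return KineticFitResult(
        tau=tau,
        tau_se=float(np.sqrt(tau_var)) if np.isfinite(tau_var) else np.nan,
        amplitude=amp,
        r_squared=r2,
        poor_fit=r2 < POOR_FIT_R2,
        converged=True,
    )


def timeseries_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Coefficient of determination of the OLS line of b on a.

    Both series must have equal length >= 3 and matched time points; used to
    compare normalized fluorescence time courses across assays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.var(a) == 0:
        raise ValueError("zero variance in predictor series")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)
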