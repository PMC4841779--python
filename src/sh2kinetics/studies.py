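"""Canned simulation studies at fixed, documented conditions.

These functions define the study conditions once — movie geometry, kinetic
constants, acquisition settings — and run the full pipeline against them.
They back both the test suite and the reproduction script so the two always
execute identical protocols.

Conditions (see docs/methods.md for the reasoning):

* tracking study: dispersed sites, no rebinding, 128x128 px at 0.16 um/px,
  5 Hz, activation density 0.015/um^2, k_off_true = 1/s, k_bleach = 0.2/s,
  D_bound = 0.021 um^2/s; several movies are pooled to pass 3000
  trajectories.
* rebinding-contrast study: two arms differing only in clustering
  (clustered_fraction_max 0.8 vs 0), analyzed on ground-truth event logs;
  per-replicate apparent off-rate and recruitment time constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sh2kinetics.config import SimulationConfig
from sh2kinetics import locfit
from sh2kinetics.kinetics import (
    estimate_lambda_off,
    fit_exponential_dwells,
    fit_recovery,
)
from sh2kinetics.simkit import (
    render_movie,
    simulate_phosphosite_dynamics,
    simulate_sh2_binding,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2**31 derived from one master seed."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


# ----------------------------------------------------------------------
# Tracking study (dispersed, no rebinding)
# ----------------------------------------------------------------------

def tracking_study_config(seed: int = 0) -> SimulationConfig:
    """Movie conditions for estimator-recovery runs on dispersed sites."""
    return SimulationConfig(
        field_size=20.48,
        pixel_size=0.16,
        frame_interval=0.2,
        n_frames=600,
        n_sites=300,
        tau_phospho=5.0,
        tau_cluster=70.0,
        cluster_count=10,
        cluster_radius=0.2,
        clustered_fraction_max=0.0,
        k_on_intrinsic=6.4e-5,
        sh2_concentration=3900.0,
        k_off_true=1.0,
        D_bound=0.021,
        rebind_capture_radius=0.1,
        rebind_probability=0.0,
        k_bleach=0.2,
        activation_density=0.015,
        psf_sigma=0.2,
        photons_per_molecule=800.0,
        background_photons=10.0,
        read_noise_sd=2.0,
        seed=seed,
    )


def run_tracking_study(seed: int, n_movies: int = 4, snr_threshold: float = 5.0) -> dict:
    """Simulate, render and track ``n_movies`` dispersed movies; pool tracks.

    Returns the pooled trajectory table plus diffusion and apparent-off-rate
    estimates against the configured ground truth.
    """
    seeds = _child_seeds(seed, n_movies)
    pooled = []
    config = None
    for i, s in enumerate(seeds):
        config = tracking_study_config(seed=s)
        field = simulate_phosphosite_dynamics(config)
        log = simulate_sh2_binding(field, config)
        movie = render_movie(log, config)
        locs = locfit.detect_movie(movie, config.psf_sigma, snr_threshold)
        max_disp = locfit.default_max_displacement(
            config.D_bound, config.frame_interval
        )
        tracks = locfit.link_trajectories(
            locs, max_disp, field_area=config.field_area
        )
        tracks["track_id"] += i * 10_000_000
        pooled.append(tracks)
    trajectories = pd.concat(pooled, ignore_index=True)

    msd = locfit.compute_msd(
        trajectories, config.frame_interval, max_lag=8, min_length=5
    )
    lam = estimate_lambda_off(
        trajectories,
        k_bleach=config.k_bleach,
        frame_interval=config.frame_interval,
        n_frames=config.n_frames,
    )
    n_tracks = trajectories["track_id"].nunique()
    return {
        "config": config,
        "trajectories": trajectories,
        "n_trajectories": int(n_tracks),
        "msd": msd,
        "D_estimate": msd.D,
        "D_true": config.D_bound,
        "lambda_off": lam,
        "lambda_off_estimate": lam.lambda_off,
        "k_off_true": config.k_off_true,
    }


# ----------------------------------------------------------------------
# Rebinding-contrast study (ground truth, clustered vs dispersed)
# ----------------------------------------------------------------------

def rebind_study_config(seed: int = 0, clustered: bool = True) -> SimulationConfig:
    """Ground-truth study arm; the two arms differ only in clustering."""
    return SimulationConfig(
        field_size=12.8,
        pixel_size=0.16,
        frame_interval=0.5,
        n_frames=480,
        n_sites=200,
        tau_phospho=25.0,
        tau_cluster=70.0,
        cluster_count=8,
        cluster_radius=0.2,
        clustered_fraction_max=0.8 if clustered else 0.0,
        k_on_intrinsic=5.1e-5,
        sh2_concentration=3900.0,
        k_off_true=1.0,
        D_bound=0.021,
        rebind_capture_radius=0.1,
        rebind_probability=0.3,
        k_bleach=0.0,
        activation_density=0.015,
        psf_sigma=0.2,
        seed=seed,
    )


def run_rebind_replicate(seed: int, clustered: bool) -> dict:
    """One ground-truth replicate: apparent off-rate from observed dwells
    and recruitment time constant from the occupancy recovery fit."""
    config = rebind_study_config(seed=seed, clustered=clustered)
    field = simulate_phosphosite_dynamics(config)
    log = simulate_sh2_binding(field, config, record_positions=False)
    events = log.to_events_dataframe()
    lam, _ = fit_exponential_dwells(
        events["dwell_true_s"].to_numpy(), events["censored"].to_numpy()
    )
    fit = fit_recovery(log.frame_times, log.occupancy.astype(float))
    return {
        "scenario": "clustered" if clustered else "dispersed",
        "seed": seed,
        "lambda_off_per_s": lam,
        "tau_recruit_s": fit.tau,
        "r_squared": fit.r_squared,
        "n_events": len(events),
        "mean_rebinds": float(events["n_rebinds"].mean()),
    }


def run_rebind_study(seed: int, n_replicates: int = 20) -> pd.DataFrame:
    """Matched clustered/dispersed replicates (same sub-seed per pair)."""
    rows = []
    for s in _child_seeds(seed, n_replicates):
        rows.append(run_rebind_replicate(s, clustered=True))
        rows.append(run_rebind_replicate(s, clustered=False))
    return pd.DataFrame(rows)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
    return float(np.quantile(means, alpha / 2)), float(np.quantile(means, 1 - alpha / 2))


# ----------------------------------------------------------------------
# Recovery-fit Monte Carlo
# ----------------------------------------------------------------------

def run_tau_recovery_mc(
    seed: int,
    n_series: int = 200,
    tau_true: float = 4.58,
    noise_sd: float = 0.05,
    n_points: int = 60,
) -> dict:
    """Monte-Carlo tau recovery: noisy first-order recovery series spanning
    3 tau (default: the GRB2-like 4.58 min constant), refit per series."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 3.0 * tau_true, n_points)
    errors = []
    for _ in range(n_series):
        y = 1.0 - np.exp(-t / tau_true) + rng.normal(0.0, noise_sd, n_points)
        fit = fit_recovery(t, y)
        if fit.converged:
            errors.append(abs(fit.tau - tau_true) / tau_true)
    errors = np.asarray(errors)
    return {
        "tau_true": tau_true,
        "n_converged": int(len(errors)),
        "median_abs_error_frac": float(np.median(errors)),
    }


# ----------------------------------------------------------------------
# Standard rate profiles for solver cross-validation
# ----------------------------------------------------------------------

def standard_rate_profiles() -> list[tuple]:
    """(name, gamma_on(t) [1/s], lambda_off(t) [1/s], t_grid [s]) suites
    used to cross-validate the analytic and numeric occupancy solvers:
    constant rates, rising/falling ramps, and a measured-style pair with a
    recovery-shaped on-rate and a rebinding-suppressed falling off-rate."""
    from sh2kinetics.rebindmodel import RateProfile

    t_short = np.linspace(0.0, 120.0, 121)
    t_long = np.linspace(0.0, 900.0, 181)
    profiles = [
        ("constant", lambda t: np.full_like(np.asarray(t, float), 0.5),
         lambda t: np.full_like(np.asarray(t, float), 0.1), t_short),
        ("gamma-ramp", RateProfile(np.array([0.0, 60.0, 120.0]),
                                   np.array([0.0, 1.0, 1.0])),
         lambda t: np.full_like(np.asarray(t, float), 0.2), t_short),
        ("lambda-ramp", lambda t: np.full_like(np.asarray(t, float), 0.8),
         RateProfile(np.array([0.0, 60.0, 120.0]), np.array([1.0, 0.2, 0.2])),
         t_short),
        ("measured-style",
         lambda t: 0.5 * (1.0 - np.exp(-np.asarray(t, float) / 124.8)),
         lambda t: 0.25 + 0.75 * np.exp(-np.asarray(t, float) / 300.0),
         t_long),
        ("pulse", RateProfile(np.array([0.0, 100.0, 200.0, 300.0, 900.0]),
                              np.array([0.0, 2.0, 0.1, 0.0, 0.0])),
         RateProfile(np.array([0.0, 450.0, 900.0]),
                     np.array([0.05, 0.6, 0.6])), t_long),
    ]
    return profiles
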