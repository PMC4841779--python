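"""Simulator ground truth: phosphosite dynamics, binding events, rendering."""

import numpy as np
import pandas as pd
import pytest

from sh2kinetics.config import ConfigurationError, SimulationConfig
from sh2kinetics.kinetics import fit_exponential_dwells
from sh2kinetics.simkit import (
    MovieStack,
    render_clean_frame,
    render_movie,
    simulate_phosphosite_dynamics,
    simulate_sh2_binding,
)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        field_size=10.24,
        pixel_size=0.16,
        frame_interval=0.5,
        n_frames=120,
        n_sites=80,
        tau_phospho=10.0,
        tau_cluster=40.0,
        cluster_count=4,
        cluster_radius=0.2,
        clustered_fraction_max=0.0,
        k_on_intrinsic=5e-5,
        sh2_concentration=3900.0,
        k_off_true=0.5,
        D_bound=0.02,
        rebind_probability=0.0,
        k_bleach=0.0,
        activation_density=0.05,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ----------------------------------------------------------------------
# Phosphosite field
# ----------------------------------------------------------------------

class TestPhosphositeField:
    def test_vanishing_rate_yields_no_phosphosites(self):
        cfg = small_config(tau_phospho=1e9, n_sites=500)
        field = simulate_phosphosite_dynamics(cfg)
        assert field.phosphorylated(cfg.duration).sum() == 0

    def test_zero_clustered_fraction_never_assigns_clusters(self):
        cfg = small_config(clustered_fraction_max=0.0)
        field = simulate_phosphosite_dynamics(cfg)
        for t in (0.0, 15.0, cfg.duration):
            assert (field.cluster_ids(t) == -1).all()

    def test_phospho_count_matches_bernoulli_oracle(self):
        # 1000 sites, tau 60 s, queried at t = 60 s: expect ~632
        cfg = small_config(n_sites=1000, tau_phospho=60.0, seed=11)
        field = simulate_phosphosite_dynamics(cfg)
        count = int(field.phosphorylated(60.0).sum())
        p = 1.0 - np.exp(-1.0)
        sd = np.sqrt(1000 * p * (1 - p))
        assert abs(count - 1000 * p) < 4 * sd
        # independent Bernoulli resampling oracle
        oracle = np.random.default_rng(123)
        counts = (oracle.random((500, 1000)) < p).sum(axis=1)
        assert abs(count - counts.mean()) < 4 * sd

    def test_phosphorylation_is_monotone_without_decay(self):
        field = simulate_phosphosite_dynamics(small_config())
        counts = [field.phosphorylated(t).sum() for t in np.linspace(0, 60, 30)]
        assert (np.diff(counts) >= 0).all()

    def test_dephosphorylation_gate_produces_decay(self):
        cfg = small_config(tau_dephospho=5.0, tau_phospho=2.0)
        field = simulate_phosphosite_dynamics(cfg)
        peak = max(field.phosphorylated(t).sum() for t in np.linspace(0, 20, 40))
        assert field.phosphorylated(cfg.duration).sum() < peak

    def test_cluster_capacity_validation(self):
        with pytest.raises(ConfigurationError):
            small_config(cluster_count=4, sites_per_cluster=30, n_sites=80)

    def test_cluster_geometry_and_fraction(self):
        cfg = small_config(clustered_fraction_max=0.8, tau_phospho=1e-3, seed=3)
        field = simulate_phosphosite_dynamics(cfg)
        L = cfg.field_size
        assert np.all((field.cluster_centers >= 0) & (field.cluster_centers <= L))
        t_late = 10 * cfg.tau_cluster
        ids = field.cluster_ids(t_late)
        frac = np.mean(ids >= 0)
        assert abs(frac - 0.8) < 0.15
        clustered = ids >= 0
        dist = np.hypot(
            *(field.positions(t_late)[clustered] - field.cluster_centers[ids[clustered]]).T
        )
        assert dist.max() <= cfg.cluster_radius + 1e-9


# ----------------------------------------------------------------------
# Binding simulation
# ----------------------------------------------------------------------

class TestBindingSimulation:
    def test_zero_on_rate_gives_empty_log(self):
        cfg = small_config(k_on_intrinsic=0.0)
        log = simulate_sh2_binding(simulate_phosphosite_dynamics(cfg), cfg)
        assert log.n_molecules == 0
        assert (log.occupancy == 0).all()

    def test_irreversible_single_site_event_is_censored(self):
        cfg = small_config(
            n_sites=1, k_off_true=0.0, k_bleach=0.0, tau_phospho=1e-3,
            k_on_intrinsic=1.0,
        )
        log = simulate_sh2_binding(simulate_phosphosite_dynamics(cfg), cfg)
        assert log.n_molecules == 1
        assert log.events[0].censored
        assert log.occupancy[-1] == 1

    def test_dwell_mle_recovers_off_rate_on_dispersed_sites(self):
        cfg = small_config(
            field_size=20.48, n_sites=300, tau_phospho=2.0, n_frames=240,
            k_on_intrinsic=6.4e-5, k_off_true=0.5, D_bound=0.0, seed=21,
        )
        log = simulate_sh2_binding(
            simulate_phosphosite_dynamics(cfg), cfg, record_positions=False
        )
        ev = log.to_events_dataframe()
        assert len(ev) >= 3000
        lam, _ = fit_exponential_dwells(
            ev["dwell_true_s"].to_numpy(), ev["censored"].to_numpy()
        )
        assert abs(lam - 0.5) / 0.5 < 0.10

    def test_event_accounting_and_occupancy_bounds(self):
        cfg = small_config(seed=9)
        field = simulate_phosphosite_dynamics(cfg)
        log = simulate_sh2_binding(field, cfg, record_positions=False)
        ev = log.to_events_dataframe()
        # conservation: every molecule is either still bound (censored) or has
        # returned to the pool with a definite unbind time
        assert ev["censored"].equals(ev["unbind_time_s"].isna())
        uncensored = ev[~ev["censored"]]
        assert (uncensored["unbind_time_s"] > uncensored["bind_time_s"]).all()
        assert int(ev["censored"].sum()) + len(uncensored) == log.n_molecules
        # occupancy never exceeds the phosphorylated-site count
        for i, t in enumerate(log.frame_times):
            assert log.occupancy[i] <= field.phosphorylated(t).sum()
        # occupancy recomputed from event intervals matches the recorded
        # curve (frames record before same-instant reactions, so binding at
        # exactly the frame time is not yet visible, unbinding still is)
        recomputed = np.array(
            [
                np.sum(
                    (ev["bind_time_s"] < t)
                    & (ev["unbind_time_s"].fillna(np.inf) >= t)
                )
                for t in log.frame_times
            ]
        )
        assert (recomputed == log.occupancy).all()

    def test_mean_occupancy_matches_constant_rate_closed_form(self):
        # low per-site occupancy so the non-depleting closed form applies
        base = small_config(
            n_sites=1000, tau_phospho=1e-3, k_on_intrinsic=5.13e-6,
            k_off_true=0.5, D_bound=0.0, n_frames=120,
        )
        gamma = base.n_sites * base.binding_rate_per_site
        lam = base.k_off_true
        curves = []
        for s in range(50):
            cfg = base.replace(seed=1000 + s)
            log = simulate_sh2_binding(
                simulate_phosphosite_dynamics(cfg), cfg, record_positions=False
            )
            curves.append(log.occupancy)
        mean_occ = np.mean(curves, axis=0)
        t = base.frame_times()
        expected = gamma / lam * (1.0 - np.exp(-lam * t))
        steady = gamma / lam
        late = t > 2.0 / lam
        assert abs(mean_occ[late].mean() - steady) / steady < 0.05
        rms = np.sqrt(np.mean((mean_occ[1:] - expected[1:]) ** 2))
        assert rms / steady < 0.06

    def test_rebinding_extends_dwell_in_clustered_fields(self, rebind_study):
        by = rebind_study.groupby("scenario")
        assert by["mean_rebinds"].mean()["clustered"] > by["mean_rebinds"].mean()["dispersed"]
        assert (
            by["lambda_off_per_s"].mean()["clustered"]
            < by["lambda_off_per_s"].mean()["dispersed"]
        )

    def test_identical_seed_reproduces_bit_identical_log(self):
        cfg = small_config(clustered_fraction_max=0.5, rebind_probability=0.3,
                           k_bleach=0.1, seed=17)
        runs = []
        for _ in range(2):
            field = simulate_phosphosite_dynamics(cfg)
            runs.append(simulate_sh2_binding(field, cfg))
        a, b = runs
        pd.testing.assert_frame_equal(a.to_events_dataframe(), b.to_events_dataframe())
        assert (a.occupancy == b.occupancy).all()
        movie_a = render_movie(a, cfg)
        movie_b = render_movie(b, cfg)
        assert (movie_a.frames == movie_b.frames).all()


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------

class TestRendering:
    def test_empty_log_renders_pure_background(self):
        cfg = small_config(k_on_intrinsic=0.0, n_frames=20)
        log = simulate_sh2_binding(simulate_phosphosite_dynamics(cfg), cfg)
        movie = render_movie(log, cfg)
        assert abs(movie.frames.mean() - cfg.background_photons) < 0.2

    def test_single_molecule_peaks_at_its_pixel(self):
        cfg = small_config()
        x, y = 5.00, 3.30
        clean = render_clean_frame(np.array([[x, y]]), cfg)
        r, c = np.unravel_index(np.argmax(clean), clean.shape)
        assert c == int(x / cfg.pixel_size)
        assert r == int(y / cfg.pixel_size)

    def test_rendered_signal_integrates_to_photon_budget(self):
        cfg = small_config(photons_per_molecule=500.0)
        clean = render_clean_frame(np.array([[5.0, 5.0]]), cfg)
        assert abs(clean.sum() - 500.0) / 500.0 < 0.005

    def test_psf_support_exceeding_grid_raises(self):
        cfg = small_config(field_size=0.96, n_sites=1)  # 6 px grid, 11 px support
        log = simulate_sh2_binding(simulate_phosphosite_dynamics(cfg), cfg)
        with pytest.raises(ValueError, match="PSF support"):
            render_movie(log, cfg)

    def test_tiff_roundtrip_preserves_frames_and_metadata(self, tmp_path):
        cfg = small_config(n_frames=5)
        log = simulate_sh2_binding(simulate_phosphosite_dynamics(cfg), cfg)
        movie = render_movie(log, cfg)
        path = tmp_path / "movie.tif"
        movie.save(path)
        loaded = MovieStack.load(path)
        assert loaded.frames.dtype == np.uint16
        assert (loaded.frames == movie.frames).all()
        assert loaded.pixel_size == cfg.pixel_size
        assert loaded.frame_interval == cfg.frame_interval


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_off_true": -0.1},
            {"tau_phospho": 0.0},
            {"rebind_probability": 1.5},
            {"clustered_fraction_max": -0.2},
            {"n_frames": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            small_config(**kwargs)

    def test_high_activation_density_warns(self):
        with pytest.warns(UserWarning, match="mistracking"):
            small_config(activation_density=0.2)

    def test_yaml_roundtrip(self, tmp_path):
        from sh2kinetics.config import load_config

        cfg = small_config(seed=42)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        assert load_config(path) == cfg
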