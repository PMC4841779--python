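"""Shared fixtures.

The expensive simulation studies run once per session and feed both the
module tests and the acceptance suite: a pooled dispersed-site tracking study
(estimator recovery), a clustered-vs-dispersed ground-truth replicate study
(the rebinding phenotype), and one fully rendered clustered acquisition
(segmentation and partitioning against ground truth).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sh2kinetics import locfit
from sh2kinetics.clusterfield import segment_clusters
from sh2kinetics.pipeline import run_scenario, scenario_config
from sh2kinetics.simkit import (
    choose_activated,
    render_movie,
    simulate_phosphosite_dynamics,
    simulate_sh2_binding,
)
from sh2kinetics.simkit.render import visible_molecule_table
from sh2kinetics.studies import run_rebind_study, run_tracking_study


@pytest.fixture(scope="session")
def tracking_study() -> dict:
    """Dispersed, no-rebinding movies tracked end to end (>=3000 tracks)."""
    return run_tracking_study(seed=1, n_movies=4)


@pytest.fixture(scope="session")
def rebind_study() -> pd.DataFrame:
    """20 matched clustered/dispersed ground-truth replicates."""
    return run_rebind_study(seed=1, n_replicates=20)


@pytest.fixture(scope="session")
def clustered_imaging_run() -> dict:
    """One rendered clustered acquisition with every intermediate exposed."""
    config = scenario_config("egf-clustered", seed=3)
    field = simulate_phosphosite_dynamics(config)
    log = simulate_sh2_binding(field, config)
    activated = choose_activated(log, config)
    movie = render_movie(log, config, activated)
    bulk_movie = render_movie(log, config, bulk=True)
    visible = visible_molecule_table(log, config, activated)
    locs = locfit.detect_movie(movie, config.psf_sigma, 5.0)
    max_disp = locfit.default_max_displacement(config.D_bound, config.frame_interval)
    tracks = locfit.link_trajectories(locs, max_disp, field_area=config.field_area)
    late_start = bulk_movie.n_frames - int(round(60.0 / config.frame_interval))
    late_mean = bulk_movie.frames[late_start:].mean(axis=0)
    mask = segment_clusters(late_mean, config.pixel_size, config.psf_sigma)
    return {
        "config": config,
        "field": field,
        "log": log,
        "activated": activated,
        "visible": visible,
        "movie": movie,
        "bulk_movie": bulk_movie,
        "tracks": tracks,
        "mask": mask,
    }


@pytest.fixture(scope="session")
def egf_run(tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("egf")
    manifest, summary = run_scenario("egf-clustered", seed=3, out_dir=out)
    return {"manifest": manifest, "summary": summary, "out_dir": out}


@pytest.fixture(scope="session")
def pv_run(tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("pv")
    manifest, summary = run_scenario("pv-dispersed", seed=4, out_dir=out)
    return {"manifest": manifest, "summary": summary, "out_dir": out}
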