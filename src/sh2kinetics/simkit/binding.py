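"""Stochastic single-molecule SH2 binding with local rebinding.

Hybrid fixed-step scheme: the frame interval is subdivided SUBSTEPS-fold and
reactions (capture, dissociation, bleaching) are drawn per substep from their
exponential waiting-time probabilities while bound molecules take Brownian
steps.  On dissociation a molecule attempts recapture by free phosphosites
within ``rebind_capture_radius`` (nearest first, one Bernoulli trial per
site); failure returns it to the well-mixed cytosolic reservoir.  Bleaching
ends observability, never ground-truth occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sh2kinetics.config import ConfigurationError, SimulationConfig
from sh2kinetics.simkit.field import PhosphositeField

#: Substeps per camera frame for the reaction/diffusion stepping.
SUBSTEPS = 10


@dataclass
class BindingEvent:
    """One membrane visit of one molecule (rebinding hops included)."""

    molecule_id: int
    bind_time: float                 # s
    unbind_time: float | None        # s; None = censored at movie end
    bleach_time: float | None        # s; None = never bleached
    site_ids: list                   # sites visited, in order
    start_clustered: bool            # first site cluster-resident at bind time
    frames: np.ndarray | None = None  # frame indices while bound (if recorded)
    xy: np.ndarray | None = None      # (len(frames), 2) positions, um

    @property
    def censored(self) -> bool:
        return self.unbind_time is None

    @property
    def n_rebinds(self) -> int:
        return len(self.site_ids) - 1

    def dwell_true(self, t_end: float) -> float:
        """Ground-truth membrane dwell (censored events run to movie end)."""
        return (self.unbind_time if self.unbind_time is not None else t_end) - self.bind_time

    def dwell_observed(self, t_end: float) -> float:
        """Observable dwell: terminated by unbinding, bleaching or movie end."""
        stop = t_end
        if self.unbind_time is not None:
            stop = min(stop, self.unbind_time)
        if self.bleach_time is not None:
            stop = min(stop, self.bleach_time)
        return stop - self.bind_time


@dataclass
class BindingEventLog:
    """Every membrane visit plus the ground-truth occupancy time course."""

    events: list
    occupancy: np.ndarray        # bound count at each frame time
    frame_times: np.ndarray      # s
    config: SimulationConfig

    @property
    def n_molecules(self) -> int:
        return len(self.events)

    def to_events_dataframe(self) -> pd.DataFrame:
        t_end = self.config.duration
        rows = [
            {
                "molecule_id": e.molecule_id,
                "bind_time_s": e.bind_time,
                "unbind_time_s": np.nan if e.unbind_time is None else e.unbind_time,
                "censored": e.censored,
                "bleach_time_s": np.nan if e.bleach_time is None else e.bleach_time,
                "n_rebinds": e.n_rebinds,
                "start_clustered": e.start_clustered,
                "dwell_true_s": e.dwell_true(t_end),
                "dwell_observed_s": e.dwell_observed(t_end),
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "molecule_id", "bind_time_s", "unbind_time_s", "censored",
                "bleach_time_s", "n_rebinds", "start_clustered",
                "dwell_true_s", "dwell_observed_s",
            ],
        )

    def save_events_csv(self, path: str | Path) -> None:
        self.to_events_dataframe().to_csv(path, index=False)

    def to_trajectories(self, observable_only: bool = True) -> pd.DataFrame:
        """Ground-truth trajectory table in the tracking dialect.

        Requires the simulation to have recorded per-frame positions.  With
        ``observable_only`` frames after a molecule's bleach time are dropped
        (what a camera would see of a perfectly detected movie).
        """
        frames_out, ids, xs, ys = [], [], [], []
        for e in self.events:
            if e.frames is None:
                raise ValueError(
                    "positions were not recorded; rerun simulate_sh2_binding "
                    "with record_positions=True"
                )
            keep = np.ones(len(e.frames), dtype=bool)
            if observable_only and e.bleach_time is not None:
                keep = self.frame_times[e.frames] < e.bleach_time
            frames_out.append(e.frames[keep])
            xs.append(e.xy[keep, 0])
            ys.append(e.xy[keep, 1])
            ids.append(np.full(int(keep.sum()), e.molecule_id))
        if not frames_out:
            return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
        df = pd.DataFrame(
            {
                "track_id": np.concatenate(ids),
                "frame": np.concatenate(frames_out),
                "x_um": np.concatenate(xs),
                "y_um": np.concatenate(ys),
            }
        )
        return df[df.groupby("track_id")["frame"].transform("size") > 0].reset_index(drop=True)


def simulate_sh2_binding(
    field: PhosphositeField,
    config: SimulationConfig,
    record_positions: bool = True,
) -> BindingEventLog:
    """Event-driven stochastic simulation of SH2 capture/release/rebinding.

    Free phosphorylated sites capture cytosolic molecules at rate
    ``k_on_intrinsic * sh2_concentration`` per site; bound molecules diffuse
    with ``D_bound``, dissociate at ``k_off_true`` and locally rebind, and
    bleach at ``k_bleach``.  Reproducible bit-for-bit given config.seed (uses
    the ``binding`` substream).  An empty field yields an empty log.
    """
    if field.n_sites != config.n_sites:
        raise ConfigurationError("field geometry does not match config")

    rng = config.rng("binding")
    dt = config.frame_interval / SUBSTEPS
    n_steps = config.n_frames * SUBSTEPS
    L = config.field_size

    p_bind = 1.0 - np.exp(-config.binding_rate_per_site * dt)
    p_off = 1.0 - np.exp(-config.k_off_true * dt)
    p_bleach = 1.0 - np.exp(-config.k_bleach * dt)
    step_sd = np.sqrt(2.0 * config.D_bound * dt)
    capture_r2 = config.rebind_capture_radius ** 2

    site_occupied = np.zeros(field.n_sites, dtype=bool)

    # Per-molecule records (grow-only).
    bind_time: list[float] = []
    unbind_time: list = []
    bleach_time: list = []
    site_ids: list[list[int]] = []
    start_clustered: list[bool] = []
    rec_frames: list[list[int]] = []
    rec_xy: list[list[tuple]] = []

    # Active (currently bound) molecule state.
    act_mol = np.empty(0, dtype=int)
    act_site = np.empty(0, dtype=int)
    act_x = np.empty(0)
    act_y = np.empty(0)
    act_bleached = np.empty(0, dtype=bool)

    occupancy = np.zeros(config.n_frames, dtype=int)
    frame_times = config.frame_times()

    for step in range(n_steps):
        t = step * dt

        # Frame boundary: record state *at* t = frame * frame_interval.
        if step % SUBSTEPS == 0:
            f = step // SUBSTEPS
            occupancy[f] = len(act_mol)
            if record_positions:
                for m, x, y in zip(act_mol, act_x, act_y):
                    rec_frames[m].append(f)
                    rec_xy[m].append((x, y))

        phospho = field.phosphorylated(t)
        clustered = field.clustered(t)
        site_pos = np.where(clustered[:, None], field.cluster_xy, field.dispersed_xy)

        # --- dissociation + local rebinding -------------------------------
        if len(act_mol):
            dissociating = rng.random(len(act_mol)) < p_off
            if dissociating.any():
                keep = np.ones(len(act_mol), dtype=bool)
                for i in np.flatnonzero(dissociating):
                    m = act_mol[i]
                    site_occupied[act_site[i]] = False
                    free = phospho & ~site_occupied
                    d2 = (
                        (site_pos[:, 0] - act_x[i]) ** 2
                        + (site_pos[:, 1] - act_y[i]) ** 2
                    )
                    candidates = np.flatnonzero(free & (d2 <= capture_r2))
                    rebound = False
                    if len(candidates) and config.rebind_probability > 0.0:
                        for s in candidates[np.argsort(d2[candidates], kind="stable")]:
                            if rng.random() < config.rebind_probability:
                                site_occupied[s] = True
                                act_site[i] = s
                                act_x[i], act_y[i] = site_pos[s]
                                site_ids[m].append(int(s))
                                rebound = True
                                break
                    if not rebound:
                        unbind_time[m] = t
                        keep[i] = False
                if not keep.all():
                    act_mol = act_mol[keep]
                    act_site = act_site[keep]
                    act_x = act_x[keep]
                    act_y = act_y[keep]
                    act_bleached = act_bleached[keep]

        # --- bleaching (observability only) -------------------------------
        if len(act_mol) and p_bleach > 0.0:
            fresh = ~act_bleached
            if fresh.any():
                hits = fresh & (rng.random(len(act_mol)) < p_bleach)
                for i in np.flatnonzero(hits):
                    bleach_time[act_mol[i]] = t
                act_bleached |= hits

        # --- new capture on free phosphorylated sites ---------------------
        free_sites = np.flatnonzero(phospho & ~site_occupied)
        if len(free_sites) and p_bind > 0.0:
            captured = free_sites[rng.random(len(free_sites)) < p_bind]
            if len(captured):
                site_occupied[captured] = True
                new_ids = np.arange(len(bind_time), len(bind_time) + len(captured))
                for s in captured:
                    bind_time.append(t)
                    unbind_time.append(None)
                    bleach_time.append(None)
                    site_ids.append([int(s)])
                    start_clustered.append(bool(clustered[s]))
                    rec_frames.append([])
                    rec_xy.append([])
                act_mol = np.concatenate([act_mol, new_ids])
                act_site = np.concatenate([act_site, captured])
                act_x = np.concatenate([act_x, site_pos[captured, 0]])
                act_y = np.concatenate([act_y, site_pos[captured, 1]])
                act_bleached = np.concatenate(
                    [act_bleached, np.zeros(len(captured), dtype=bool)]
                )

        # --- bound-state diffusion (reflecting boundaries) -----------------
        if len(act_mol) and step_sd > 0.0:
            act_x = np.abs(act_x + rng.normal(0.0, step_sd, len(act_mol)))
            act_y = np.abs(act_y + rng.normal(0.0, step_sd, len(act_mol)))
            act_x = L - np.abs(L - act_x)
            act_y = L - np.abs(L - act_y)

    events = [
        BindingEvent(
            molecule_id=m,
            bind_time=bind_time[m],
            unbind_time=unbind_time[m],
            bleach_time=bleach_time[m],
            site_ids=site_ids[m],
            start_clustered=start_clustered[m],
            frames=np.asarray(rec_frames[m], dtype=int) if record_positions else None,
            xy=np.asarray(rec_xy[m], dtype=float).reshape(-1, 2)
            if record_positions
            else None,
        )
        for m in range(len(bind_time))
    ]
    return BindingEventLog(
        events=events, occupancy=occupancy, frame_times=frame_times, config=config
    )
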