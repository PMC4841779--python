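"""Ground-truth phosphosite field dynamics.

Each binding site carries a stochastic activation time (first-order
phosphorylation, time constant ``tau_phospho``) and a clustering quantile: at
time t a fraction ``clustered_fraction_max * (1 - exp(-t/tau_cluster))`` of
the phosphorylated sites has relocated from its dispersed position into one of
``cluster_count`` disc-shaped clusters.  The field is stored lazily — per-site
draws plus closed-form ramps — so any time point can be queried in O(n_sites)
without materializing a per-frame site list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sh2kinetics.config import SimulationConfig


@dataclass
class PhosphositeField:
    """Binding-site positions, phosphorylation state and cluster membership.

    Attributes
    ----------
    dispersed_xy : (n_sites, 2) float array, um
        Site position while not clustered (uniform over the field).
    cluster_xy : (n_sites, 2) float array, um
        Target position inside the assigned cluster disc.
    cluster_assignment : (n_sites,) int array
        Index of the assigned cluster, or -1 for sites that never cluster.
    cluster_centers : (cluster_count, 2) float array, um
    t_phospho : (n_sites,) float array, s
        Stochastic phosphorylation time of each site (may exceed the movie).
    t_dephospho : (n_sites,) float array or None, s
        Optional decay time (config-gated; None when dephosphorylation is off).
    u_cluster : (n_sites,) float array
        Clustering quantile in [0, 1); a site is clustered at time t iff it is
        phosphorylated and u_cluster < clustered_fraction(t).
    """

    dispersed_xy: np.ndarray
    cluster_xy: np.ndarray
    cluster_assignment: np.ndarray
    cluster_centers: np.ndarray
    t_phospho: np.ndarray
    t_dephospho: np.ndarray | None
    u_cluster: np.ndarray
    field_size: float
    tau_cluster: float
    clustered_fraction_max: float

    @property
    def n_sites(self) -> int:
        return len(self.t_phospho)

    # ------------------------------------------------------------------
    def phosphorylated(self, t: float) -> np.ndarray:
        """Boolean mask of sites phosphorylated at time ``t`` (s)."""
        on = self.t_phospho <= t
        if self.t_dephospho is not None:
            on &= t < self.t_dephospho
        return on

    def clustered_fraction(self, t: float) -> float:
        """Target fraction of phosphorylated sites residing in clusters."""
        return self.clustered_fraction_max * (1.0 - np.exp(-t / self.tau_cluster))

    def clustered(self, t: float) -> np.ndarray:
        """Mask of sites that are phosphorylated *and* cluster-resident."""
        return self.phosphorylated(t) & (self.u_cluster < self.clustered_fraction(t))

    def cluster_ids(self, t: float) -> np.ndarray:
        """Per-site cluster id at time t; -1 means not in any cluster."""
        ids = np.where(self.clustered(t), self.cluster_assignment, -1)
        return ids

    def positions(self, t: float) -> np.ndarray:
        """(n_sites, 2) site positions at time t (clustered sites relocated)."""
        mask = self.clustered(t)[:, None]
        return np.where(mask, self.cluster_xy, self.dispersed_xy)

    def snapshot(self, t: float) -> pd.DataFrame:
        xy = self.positions(t)
        return pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "phosphorylated": self.phosphorylated(t),
                "cluster_id": self.cluster_ids(t),
            }
        )

    def to_sites_dataframe(self) -> pd.DataFrame:
        """Static per-site table (dispersed position, activation time,
        assigned cluster)."""
        return pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "x_um": self.dispersed_xy[:, 0],
                "y_um": self.dispersed_xy[:, 1],
                "t_phospho_s": self.t_phospho,
                "cluster_id": self.cluster_assignment,
            }
        )

    def save_sites_csv(self, path: str | Path) -> None:
        self.to_sites_dataframe().to_csv(path, index=False)


def simulate_phosphosite_dynamics(config: SimulationConfig) -> PhosphositeField:
    """Draw a phosphosite field from the configured creation/clustering model.

    Deterministic given ``config.seed`` (uses the ``phospho`` substream).
    Phosphorylation times are exponential with mean ``tau_phospho``, so the
    cumulative per-site activation probability at time t is 1 - exp(-t/tau).
    Cluster centers are uniform with a one-radius margin so every disc lies
    inside the field.
    """
    rng = config.rng("phospho")
    n = config.n_sites
    L = config.field_size

    dispersed_xy = rng.uniform(0.0, L, size=(n, 2))
    t_phospho = rng.exponential(config.tau_phospho, size=n)
    t_dephospho = None
    if config.tau_dephospho is not None:
        t_dephospho = t_phospho + rng.exponential(config.tau_dephospho, size=n)
    u_cluster = rng.uniform(0.0, 1.0, size=n)

    margin = min(config.cluster_radius, L / 2)
    centers = rng.uniform(margin, L - margin, size=(config.cluster_count, 2))

    if config.sites_per_cluster is None:
        # balanced assignment: clusters receive equal site shares (a seeded
        # permutation decides which sites), so no cluster is systematically
        # dimmer than its peers
        assignment = np.empty(n, dtype=int)
        assignment[rng.permutation(n)] = np.arange(n) % config.cluster_count
    else:
        # Capacity-limited: shuffled round-robin fill; overflow sites never
        # join a cluster.
        assignment = np.full(n, -1, dtype=int)
        order = rng.permutation(n)
        capacity = config.cluster_count * config.sites_per_cluster
        eligible = order[:capacity]
        assignment[eligible] = np.arange(len(eligible)) % config.cluster_count
        u_cluster = u_cluster.copy()
        u_cluster[assignment < 0] = np.inf  # can never satisfy u < fraction

    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    r = config.cluster_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    safe_assignment = np.where(assignment >= 0, assignment, 0)
    cluster_xy = centers[safe_assignment] + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)]
    )
    cluster_xy = np.clip(cluster_xy, 0.0, L)

    return PhosphositeField(
        dispersed_xy=dispersed_xy,
        cluster_xy=cluster_xy,
        cluster_assignment=assignment,
        cluster_centers=centers,
        t_phospho=t_phospho,
        t_dephospho=t_dephospho,
        u_cluster=u_cluster,
        field_size=L,
        tau_cluster=config.tau_cluster,
        clustered_fraction_max=config.clustered_fraction_max,
    )
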