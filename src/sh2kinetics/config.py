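"""Simulation configuration.

All lengths are in micrometers, times in seconds, rates in 1/s unless a field
name says otherwise.  A single integer seed fans out into named substreams so
that e.g. changing the camera-noise draw never perturbs the binding kinetics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Substream indices hung off the master seed.  Keeping these fixed means the
#: phospho field, binding kinetics, photoactivation subset and camera noise are
#: each reproducible in isolation.
SUBSTREAMS = {"phospho": 0, "binding": 1, "activation": 2, "noise": 3}

#: Sparse-photoactivation operating range; densities above this risk
#: mistracking (nearest-neighbor linking starts swapping identities).
DENSITY_WARNING_THRESHOLD = 0.1  # molecules / um^2


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic sptPALM/TIRF acquisition.

    The defaults describe a sub-saturating EGF-style scenario on a ~20 um
    square membrane patch: phosphosites appear with first-order kinetics,
    progressively relocate into disc-shaped clusters, and capture cytosolic
    SH2 molecules which diffuse, dissociate and locally rebind.
    """

    # --- geometry / acquisition ---
    field_size: float = 20.48          # um, square field edge
    pixel_size: float = 0.16           # um / px
    frame_interval: float = 0.2        # s
    n_frames: int = 600
    # --- phosphosite field ---
    n_sites: int = 300
    tau_phospho: float = 25.0          # s, first-order site creation constant
    tau_cluster: float = 70.0          # s, clustering ramp constant
    cluster_count: int = 10
    cluster_radius: float = 0.2        # um, disc radius
    clustered_fraction_max: float = 0.8
    sites_per_cluster: int | None = None   # optional capacity check
    tau_dephospho: float | None = None     # optional first-order decay (off by default)
    # --- SH2 binding kinetics ---
    k_on_intrinsic: float = 6.4e-5     # um^3/s per site (volumetric association)
    sh2_concentration: float = 3900.0  # molecules/um^3 (~6.5 uM)
    k_off_true: float = 1.0            # 1/s
    D_bound: float = 0.021             # um^2/s, bound-state diffusion
    rebind_capture_radius: float = 0.1  # um
    rebind_probability: float = 0.3    # per free site within radius, nearest first
    # --- photophysics / camera ---
    k_bleach: float = 0.2              # 1/s
    activation_density: float = 0.015  # visible molecules / um^2 (cap)
    psf_sigma: float = 0.2             # um
    photons_per_molecule: float = 800.0
    background_photons: float = 10.0   # counts / px
    read_noise_sd: float = 2.0         # counts
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "field_size", "pixel_size", "frame_interval", "psf_sigma",
            "tau_phospho", "tau_cluster", "cluster_radius",
            "sh2_concentration",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        nonneg = [
            "k_on_intrinsic", "k_off_true", "D_bound", "k_bleach",
            "rebind_capture_radius", "photons_per_molecule",
            "background_photons", "read_noise_sd", "activation_density",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("n_frames", "n_sites", "cluster_count"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("rebind_probability", "clustered_fraction_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.tau_dephospho is not None and self.tau_dephospho <= 0:
            raise ConfigurationError("tau_dephospho must be positive when set")
        if self.sites_per_cluster is not None:
            if self.cluster_count * self.sites_per_cluster > self.n_sites:
                raise ConfigurationError(
                    "cluster_count * sites_per_cluster exceeds n_sites"
                )
        if self.activation_density > DENSITY_WARNING_THRESHOLD:
            warnings.warn(
                f"activation_density {self.activation_density:.3f}/um^2 exceeds "
                f"{DENSITY_WARNING_THRESHOLD}/um^2; risk of mistracking",
                UserWarning,
                stacklevel=2,
            )

    # ------------------------------------------------------------------
    @property
    def field_area(self) -> float:
        """Field area in um^2."""
        return self.field_size ** 2

    @property
    def n_pixels(self) -> int:
        """Pixels per edge (field truncated to whole pixels)."""
        return int(round(self.field_size / self.pixel_size))

    @property
    def duration(self) -> float:
        """Movie duration in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def binding_rate_per_site(self) -> float:
        """Pseudo-first-order capture rate of a free phosphosite, 1/s."""
        return self.k_on_intrinsic * self.sh2_concentration

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator hanging off the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(SUBSTREAMS[stream],))
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def content_hash(self) -> str:
        """sha256 of the canonical JSON form (manifest provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML config file validated against the SimulationConfig schema."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
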