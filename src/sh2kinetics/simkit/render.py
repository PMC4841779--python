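"""Camera-movie rendering of binding-event logs.

Emulates sparse-photoactivation acquisition: a seeded subset of molecules is
"activated" such that the instantaneous visible density never exceeds
``activation_density``; each visible molecule is drawn as a pixel-integrated
2D Gaussian PSF scaled to ``photons_per_molecule``; per-pixel Poisson shot
noise on signal + background plus Gaussian read noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.special import erf

from sh2kinetics.config import SimulationConfig
from sh2kinetics.simkit.binding import BindingEventLog

#: PSF support radius in sigmas used for rendering and grid-size validation.
PSF_SUPPORT_SIGMAS = 4.0


@dataclass
class MovieStack:
    """Time-ordered grayscale frames with acquisition metadata."""

    frames: np.ndarray          # (n_frames, H, W) uint16
    pixel_size: float           # um / px
    frame_interval: float       # s

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def save(self, path: str | Path) -> None:
        """Write a 16-bit multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pixel_size_um": self.pixel_size,
                    "frame_interval_s": self.frame_interval,
                    "n_frames": int(self.n_frames),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "MovieStack":
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            frames=frames,
            pixel_size=float(meta["pixel_size_um"]),
            frame_interval=float(meta["frame_interval_s"]),
        )


def _pixel_integrated_gaussian(
    image: np.ndarray, x: float, y: float, sigma_px: float, photons: float
) -> None:
    """Accumulate a unit-integral 2D Gaussian (scaled to ``photons``) onto
    ``image`` in place.  Pixel (r, c) covers [c, c+1) x [r, r+1) in pixel
    units; the erf form integrates the PSF exactly over each pixel."""
    h, w = image.shape
    half = int(np.ceil(PSF_SUPPORT_SIGMAS * sigma_px)) + 1
    c0 = max(int(np.floor(x)) - half, 0)
    c1 = min(int(np.floor(x)) + half + 1, w)
    r0 = max(int(np.floor(y)) - half, 0)
    r1 = min(int(np.floor(y)) + half + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    denom = sigma_px * np.sqrt(2.0)
    cx = np.arange(c0, c1)
    ry = np.arange(r0, r1)
    fx = 0.5 * (erf((cx + 1 - x) / denom) - erf((cx - x) / denom))
    fy = 0.5 * (erf((ry + 1 - y) / denom) - erf((ry - y) / denom))
    image[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_clean_frame(
    xy: np.ndarray, config: SimulationConfig, photons: float | None = None
) -> np.ndarray:
    """Noise-free, background-free photon image of molecules at ``xy`` (um)."""
    n_px = config.n_pixels
    sigma_px = config.psf_sigma / config.pixel_size
    if n_px < 2 * int(np.ceil(PSF_SUPPORT_SIGMAS * sigma_px)) + 1:
        raise ValueError("pixel grid smaller than the PSF support")
    image = np.zeros((n_px, n_px))
    photons = config.photons_per_molecule if photons is None else photons
    for x, y in np.atleast_2d(xy) if len(xy) else []:
        _pixel_integrated_gaussian(
            image, x / config.pixel_size, y / config.pixel_size, sigma_px, photons
        )
    return image


def choose_activated(log: BindingEventLog, config: SimulationConfig) -> np.ndarray:
    """Seeded photoactivation subset targeting the configured visible density.

    Each molecule is independently activated with a probability chosen so the
    *mean* instantaneous visible density equals ``activation_density`` (the
    experimenter's photoactivation-rate tuning).  Thinning is Bernoulli and
    therefore independent of a molecule's dwell time — a hard per-frame
    admission cap would selectively reject long-lived molecules (they span
    more frames) and bias the apparent off-rate, which is exactly the kind of
    estimator artifact this simulator exists to expose.  Instantaneous
    density consequently fluctuates around the target, as it does in a real
    acquisition.  Deterministic given config.seed (``activation`` substream).
    """
    rng = config.rng("activation")
    span_len = np.zeros(log.n_molecules, dtype=int)
    for m, e in enumerate(log.events):
        if e.frames is None:
            raise ValueError("positions were not recorded; cannot render")
        span = e.frames
        if e.bleach_time is not None:
            span = span[log.frame_times[span] < e.bleach_time]
        span_len[m] = len(span)
    total_slots = int(span_len.sum())
    target_slots = config.activation_density * config.field_area * config.n_frames
    p = min(1.0, target_slots / total_slots) if total_slots else 0.0
    return (rng.random(log.n_molecules) < p) & (span_len > 0)


def visible_molecule_table(
    log: BindingEventLog, config: SimulationConfig, activated: np.ndarray | None = None
):
    """Per-frame table of rendered (activated, unbleached) molecule positions.

    Ground truth for evaluating detection recall/precision and tracking.
    Columns: molecule_id, frame, x_um, y_um.
    """
    import pandas as pd

    if activated is None:
        activated = choose_activated(log, config)
    rows = {"molecule_id": [], "frame": [], "x_um": [], "y_um": []}
    for m in np.flatnonzero(activated):
        e = log.events[m]
        span = e.frames
        keep = slice(None)
        if e.bleach_time is not None:
            keep = log.frame_times[span] < e.bleach_time
        for f, (x, y) in zip(span[keep], e.xy[keep]):
            rows["molecule_id"].append(m)
            rows["frame"].append(int(f))
            rows["x_um"].append(x)
            rows["y_um"].append(y)
    return pd.DataFrame(rows)


def render_movie(
    log: BindingEventLog,
    config: SimulationConfig,
    activated: np.ndarray | None = None,
    bulk: bool = False,
) -> MovieStack:
    """Render a binding log as a noisy camera movie.

    Default mode emulates sptPALM: only the seeded photoactivated subset is
    drawn, and a molecule disappears once bleached.  ``bulk`` emulates the
    conventional-excitation channel used for recruitment and clustering
    quantification: every bound molecule is drawn for every bound frame
    (activation and the photoactivated-state bleach clock do not apply).
    """
    if activated is None and not bulk:
        activated = choose_activated(log, config)
    rng = config.rng("noise")
    n_px = config.n_pixels
    sigma_px = config.psf_sigma / config.pixel_size
    if n_px < 2 * int(np.ceil(PSF_SUPPORT_SIGMAS * sigma_px)) + 1:
        raise ValueError("pixel grid smaller than the PSF support")

    # Per-frame position lists for the visible subset.
    per_frame: list[list] = [[] for _ in range(config.n_frames)]
    molecule_ids = (
        range(log.n_molecules) if bulk else np.flatnonzero(activated)
    )
    for m in molecule_ids:
        e = log.events[m]
        span = e.frames
        keep = np.ones(len(span), dtype=bool)
        if not bulk and e.bleach_time is not None:
            keep = log.frame_times[span] < e.bleach_time
        for f, (x, y) in zip(span[keep], e.xy[keep]):
            per_frame[f].append((x, y))

    frames = np.empty((config.n_frames, n_px, n_px), dtype=np.uint16)
    for f in range(config.n_frames):
        clean = np.zeros((n_px, n_px))
        for x, y in per_frame[f]:
            _pixel_integrated_gaussian(
                clean,
                x / config.pixel_size,
                y / config.pixel_size,
                sigma_px,
                config.photons_per_molecule,
            )
        expected = clean + config.background_photons
        noisy = rng.poisson(expected).astype(float)
        if config.read_noise_sd > 0:
            noisy += rng.normal(0.0, config.read_noise_sd, size=noisy.shape)
        frames[f] = np.clip(np.round(noisy), 0, np.iinfo(np.uint16).max).astype(
            np.uint16
        )
    return MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )
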