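"""Single-molecule localization, nearest-neighbor tracking and MSD analysis.

Detection: matched Gaussian filtering, robust-noise thresholding of local
maxima, then sub-pixel refinement by least-squares 2D Gaussian fitting.  SNR
is defined as (filtered peak - median) / (1.4826 * MAD of the filtered
image).  Linking: greedy mutual-nearest-neighbor between consecutive frames,
no gap closing, no merging/splitting; a molecule that blinks therefore
produces separate tracks.

Trajectories are exchanged as long-format DataFrames with columns
``track_id, frame, x_um, y_um`` (plus ``intensity`` where available); the
ground-truth simulator emits the same dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from sh2kinetics.config import DENSITY_WARNING_THRESHOLD

LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um", "intensity", "snr"]
TRAJECTORY_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


# ----------------------------------------------------------------------
# Detection
# ----------------------------------------------------------------------

def _gaussian2d_fixed_sigma(coords, amplitude, x0, y0, offset, sigma):
    x, y = coords
    return (
        amplitude * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset
    ).ravel()


def detect_spots(
    image: np.ndarray,
    pixel_size: float,
    psf_sigma: float,
    threshold_snr: float = 5.0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one frame.

    Parameters
    ----------
    image : 2D array (counts)
    pixel_size : um per pixel
    psf_sigma : um; must exceed half a pixel (narrower PSFs are not sampled
        well enough for sub-pixel fitting)
    threshold_snr : local maxima of the matched-filtered image must exceed
        median + threshold_snr * robust noise

    Returns
    -------
    DataFrame with columns frame (filled with 0; caller overwrites), x_um,
    y_um, intensity (total fitted counts above offset), snr.
    """
    sigma_px = psf_sigma / pixel_size
    if sigma_px < 0.5:
        raise ValueError("psf_sigma smaller than half a pixel")
    img = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, sigma_px)

    background = np.median(smoothed)
    noise = 1.4826 * np.median(np.abs(smoothed - background))
    if noise == 0.0:
        noise = np.finfo(float).tiny
    threshold = background + threshold_snr * noise

    # Local maxima of the filtered image separated by >= ~1 sigma.
    size = 2 * max(1, int(round(sigma_px))) + 1
    is_max = (smoothed == ndimage.maximum_filter(smoothed, size=size)) & (
        smoothed > threshold
    )
    peaks = np.argwhere(is_max)

    half = max(2, int(np.ceil(3 * sigma_px)))
    h, w = img.shape
    out = {"x_px": [], "y_px": [], "intensity": [], "snr": []}
    for r, c in peaks:
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        window = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        amp0 = max(img[r, c] - background, 1.0)
        try:
            popt, _ = curve_fit(
                lambda coords, a, x0, y0, off: _gaussian2d_fixed_sigma(
                    coords, a, x0, y0, off, sigma_px
                ),
                (xx + 0.5, yy + 0.5),
                window.ravel(),
                p0=(amp0, c + 0.5, r + 0.5, background),
                maxfev=200,
            )
        except RuntimeError:
            continue
        amp, x0, y0, _ = popt
        if amp <= 0 or not (c0 <= x0 <= c1) or not (r0 <= y0 <= r1):
            continue
        out["x_px"].append(x0)
        out["y_px"].append(y0)
        out["intensity"].append(amp * 2 * np.pi * sigma_px**2)
        out["snr"].append((smoothed[r, c] - background) / noise)

    df = pd.DataFrame(out)
    if len(df):
        df = _merge_duplicates(df, sigma_px)
    return pd.DataFrame(
        {
            "frame": np.zeros(len(df), dtype=int),
            "x_um": df["x_px"].to_numpy() * pixel_size if len(df) else [],
            "y_um": df["y_px"].to_numpy() * pixel_size if len(df) else [],
            "intensity": df["intensity"].to_numpy() if len(df) else [],
            "snr": df["snr"].to_numpy() if len(df) else [],
        }
    )


def _merge_duplicates(df: pd.DataFrame, sigma_px: float) -> pd.DataFrame:
    """Collapse detections closer than one PSF sigma, keeping the brighter."""
    order = np.argsort(-df["intensity"].to_numpy(), kind="stable")
    xy = df[["x_px", "y_px"]].to_numpy()[order]
    keep_idx = []
    for i, pos in enumerate(xy):
        if all(np.hypot(*(pos - xy[j])) > sigma_px for j in keep_idx):
            keep_idx.append(i)
    return df.iloc[order[keep_idx]].reset_index(drop=True)


def detect_movie(
    stack, psf_sigma: float, threshold_snr: float = 5.0
) -> pd.DataFrame:
    """Run detect_spots over every frame of a MovieStack."""
    frames = []
    for f in range(stack.n_frames):
        locs = detect_spots(
            stack.frames[f], stack.pixel_size, psf_sigma, threshold_snr
        )
        locs["frame"] = f
        frames.append(locs)
    return pd.concat(frames, ignore_index=True)[LOCALIZATION_COLUMNS]


# ----------------------------------------------------------------------
# Linking
# ----------------------------------------------------------------------

def link_trajectories(
    localizations: pd.DataFrame,
    max_displacement: float,
    field_area: float | None = None,
) -> pd.DataFrame:
    """Greedy mutual-nearest-neighbor linking of detections into tracks.

    A detection in frame t links to one in frame t+1 iff each is the other's
    nearest neighbor within ``max_displacement`` (um).  Unmatched detections
    start new tracks; tracks end when unmatched (no gap closing).  Distance
    ties are broken by lower detection index, so the output is deterministic
    and invariant to the input row order (rows are sorted internally).

    Emits a mistracking warning when the mean per-frame density exceeds
    0.1/um^2 (``field_area`` in um^2 must be supplied for the check).
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be positive")
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(localizations.columns):
        raise ValueError(f"localizations must have columns {sorted(required)}")
    locs = localizations.sort_values(
        ["frame", "x_um", "y_um"], kind="stable"
    ).reset_index(drop=True)

    if field_area is not None and len(locs):
        density = locs.groupby("frame").size().mean() / field_area
        if density > DENSITY_WARNING_THRESHOLD:
            import warnings

            warnings.warn(
                f"mean detection density {density:.3f}/um^2 exceeds "
                f"{DENSITY_WARNING_THRESHOLD}/um^2; mistracking likely",
                UserWarning,
                stacklevel=2,
            )

    track_of = np.full(len(locs), -1, dtype=int)
    next_track = 0
    frames = locs["frame"].to_numpy()
    xy = locs[["x_um", "y_um"]].to_numpy()
    frame_index = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    all_frames = sorted(frame_index)

    for f in all_frames:
        idx = frame_index[f]
        for i in idx[track_of[idx] < 0]:
            track_of[i] = next_track
            next_track += 1
        nxt = frame_index.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        a, b = xy[idx], xy[nxt]
        tree_b = cKDTree(b)
        d_ab, j_ab = tree_b.query(a, distance_upper_bound=max_displacement)
        tree_a = cKDTree(a)
        d_ba, j_ba = tree_a.query(b, distance_upper_bound=max_displacement)
        for i_local, (d, j) in enumerate(zip(d_ab, j_ab)):
            if np.isinf(d) or j >= len(b):
                continue
            if j_ba[j] == i_local:  # mutual nearest neighbors
                track_of[nxt[j]] = track_of[idx[i_local]]

    out = locs.copy()
    out["track_id"] = track_of
    cols = TRAJECTORY_COLUMNS + [
        c for c in ("intensity", "snr") if c in out.columns
    ]
    return out[cols].sort_values(["track_id", "frame"], kind="stable").reset_index(
        drop=True
    )


def default_max_displacement(D_est: float, frame_interval: float) -> float:
    """Linking scan radius from an estimated diffusion constant.

    3 * sqrt(4 D dt): wide enough that the Brownian displacement tail beyond
    it carries ~1e-4 probability mass, so tracks are essentially never
    truncated by the search radius while remaining far below typical
    nearest-neighbor spacings in the sparse-activation regime.
    """
    return 3.0 * np.sqrt(4.0 * D_est * frame_interval)


def track_summary(trajectories: pd.DataFrame, n_frames: int | None = None) -> pd.DataFrame:
    """Per-track start/end/length table; ``censored`` flags tracks that reach
    the final frame (right-censored dwell)."""
    g = trajectories.groupby("track_id")["frame"]
    summary = pd.DataFrame(
        {"start_frame": g.min(), "end_frame": g.max(), "length": g.size()}
    ).reset_index()
    summary["censored"] = (
        summary["end_frame"] == (n_frames - 1) if n_frames is not None else False
    )
    return summary


# ----------------------------------------------------------------------
# MSD / diffusion
# ----------------------------------------------------------------------

@dataclass
class MSDResult:
    """Time-and-ensemble-averaged MSD curve and its linear-fit diffusion
    constant (MSD = 4 D dt + offset over the first fit_lags lags)."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    D: float                    # um^2/s
    intercept: float            # um^2 (localization-error offset)
    residual_norm: float        # um^2, RMS of fit residuals over fitted lags
    n_tracks: int

    @property
    def empty(self) -> bool:
        return self.n_tracks == 0


def compute_msd(
    trajectories: pd.DataFrame,
    frame_interval: float,
    max_lag: int = 10,
    min_length: int = 5,
    fit_lags: int = 4,
) -> MSDResult:
    """Ensemble/time-averaged MSD and diffusion constant.

    Only tracks of at least ``min_length`` frames contribute (default 5,
    i.e. tracks longer than 4 frames).  D comes from an unweighted linear
    fit MSD = 4*D*dt + b over the first ``fit_lags`` lags; the intercept
    absorbs the static localization-error offset.  Returns an empty result
    (n_tracks == 0, D = nan) when no track qualifies.
    """
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    n_tracks = 0
    for _, track in trajectories.groupby("track_id"):
        if len(track) < min_length:
            continue
        n_tracks += 1
        t = track.sort_values("frame")
        xy = t[["x_um", "y_um"]].to_numpy()
        for lag in range(1, min(max_lag, len(xy) - 1) + 1):
            d = xy[lag:] - xy[:-lag]
            sums[lag] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            counts[lag] += len(d)
    if n_tracks == 0:
        return MSDResult(
            lags_s=np.array([]), msd_um2=np.array([]), n_pairs=np.array([]),
            D=np.nan, intercept=np.nan, residual_norm=np.nan, n_tracks=0,
        )
    counts[0] = 1  # MSD(0) = 0 by construction
    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lags_s = np.arange(max_lag + 1) * frame_interval

    k = min(fit_lags, int(np.sum(~np.isnan(msd[1:]))))
    x = lags_s[1 : k + 1]
    y = msd[1 : k + 1]
    slope, intercept = np.polyfit(x, y, 1) if k >= 2 else (y[0] / x[0], 0.0)
    residuals = y - (slope * x + intercept)
    return MSDResult(
        lags_s=lags_s,
        msd_um2=msd,
        n_pairs=counts,
        D=slope / 4.0,
        intercept=intercept,
        residual_norm=float(np.sqrt(np.mean(residuals**2))),
        n_tracks=n_tracks,
    )


def per_track_diffusion(
    trajectories: pd.DataFrame,
    frame_interval: float,
    min_length: int = 5,
    fit_lags: int = 4,
) -> pd.DataFrame:
    """Individual-track D values (same linear MSD fit, per trajectory)."""
    rows = []
    for track_id, track in trajectories.groupby("track_id"):
        if len(track) < min_length:
            continue
        res = compute_msd(
            track, frame_interval, max_lag=fit_lags, min_length=min_length,
            fit_lags=fit_lags,
        )
        rows.append({"track_id": track_id, "D_um2_s": res.D, "n_frames": len(track)})
    return pd.DataFrame(rows, columns=["track_id", "D_um2_s", "n_frames"])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def save_localizations_csv(locs: pd.DataFrame, path: str | Path) -> None:
    locs[LOCALIZATION_COLUMNS].to_csv(path, index=False)


def save_trajectories_csv(trajectories: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in trajectories.columns if c in TRAJECTORY_COLUMNS]
    trajectories[cols].to_csv(path, index=False)


def load_trajectories_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    return df
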