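"""Temporal preprocessing for resting-state BOLD series.

The chain, in its fixed default order, is::

    discard initial volumes -> spatial smoothing -> linear detrend ->
    band-pass filter -> nuisance regression -> motion scrubbing

with head-motion realignment assumed already done upstream (the input is
expected on a common template grid). Defaults follow common resting-state
practice: discard 10 volumes, 4 mm FWHM smoothing, 0.01-0.08 Hz ideal
band-pass, Friston-24 motion expansion plus white-matter and CSF mean
signals as nuisance regressors, and scalar framewise displacement (FD,
Power convention with a 50 mm rotation radius) scrubbed at 0.2 mm with one
back and two forward neighbors removed around every exceedance.

Mean FD is always computed on the *pre-scrub* FD trace: it is a per-subject
covariate in the group model, not a property of the cleaned series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .volumes import TimeSeriesVolume

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ScrubResult:
    """Framewise displacement trace and the frames flagged for removal."""

    fd: np.ndarray  # per-frame FD in mm, fd[0] = 0 by convention
    flagged: np.ndarray  # bool per frame; True = remove before correlation
    mean_fd: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def load_motion_params(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion trace (one row per frame).

    Columns: translations tx, ty, tz in mm, then rotations rx, ry, rz in
    radians.
    """
    mp = np.loadtxt(str(path), dtype=float)
    if mp.ndim == 1:
        mp = mp[np.newaxis, :]
    if mp.shape[1] != 6:
        raise ValueError(f"motion file {path!r} must have 6 columns, got {mp.shape[1]}")
    return mp


def discard_initial(vol: TimeSeriesVolume, n: int) -> TimeSeriesVolume:
    """Drop the first ``n`` frames (magnetization-equilibration discard)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if vol.n_timepoints <= n:
        raise ValueError(
            f"cannot discard {n} frames from a {vol.n_timepoints}-frame series"
        )
    return vol.copy_with(
        data=vol.data[..., n:], timepoint_keep=vol.timepoint_keep[n:].copy()
    )


def framewise_displacement(
    motion_params: np.ndarray, head_radius_mm: float = 50.0
) -> ScrubResult:
    """Scalar FD: sum of absolute frame-to-frame translation differences plus
    ``head_radius_mm`` times the summed absolute rotation differences.

    ``mean_fd`` averages over all frames including the conventional
    ``fd[0] = 0``.  No flags are set here; see :func:`scrub_flags`.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion parameters must be (n_frames, 6)")
    if mp.shape[0] < 2:
        raise ValueError("FD needs at least 2 frames")
    d = np.abs(np.diff(mp, axis=0))
    fd = np.zeros(mp.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return ScrubResult(fd=fd, flagged=np.zeros(mp.shape[0], dtype=bool), mean_fd=float(fd.mean()))


def scrub_flags(
    fd: np.ndarray, threshold: float = 0.2, n_back: int = 1, n_forward: int = 2
) -> np.ndarray:
    """Flag every frame whose FD exceeds ``threshold`` plus ``n_back`` frames
    before and ``n_forward`` after it (windows clipped at the sequence ends)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    flagged = np.zeros(fd.shape[0], dtype=bool)
    for i in np.flatnonzero(fd > threshold):
        flagged[max(0, i - n_back) : min(fd.shape[0], i + n_forward + 1)] = True
    return flagged


def detrend_filter(
    vol: TimeSeriesVolume, low_hz: float = 0.01, high_hz: float = 0.08
) -> TimeSeriesVolume:
    """Per-voxel linear detrend followed by an ideal FFT-domain band-pass.

    The band-pass zeroes every DFT bin whose frequency falls outside
    ``[low_hz, high_hz]`` (band edges inclusive), matching the behavior of
    common resting-state toolboxes rather than an IIR design.
    """
    nyquist = 0.5 / vol.tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:.4f} Hz at TR {vol.tr_seconds} s)"
        )
    n_t = vol.n_timepoints
    if n_t < 3:
        raise ValueError("need at least 3 frames to detrend and filter")
    flat = vol.data.reshape(-1, n_t)
    detr = signal.detrend(flat, axis=1, type="linear")
    freqs = np.fft.rfftfreq(n_t, d=vol.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(detr, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_t, axis=1)
    return vol.copy_with(data=out.reshape(vol.data.shape))


def friston24(motion_params: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 rigid-body parameters, their one-frame-back values
    (first row zero), and the squares of both sets.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion parameters must be (n_frames, 6)")
    lagged = np.vstack([np.zeros((1, 6)), mp[:-1]])
    return np.hstack([mp, lagged, mp**2, lagged**2])


def _mask_mean(vol: TimeSeriesVolume, mask: TimeSeriesVolume, name: str) -> np.ndarray:
    if not vol.geometry.matches(mask.geometry):
        raise ValueError(f"{name} mask geometry does not match volume geometry")
    m = mask.data[..., 0] != 0
    if not m.any():
        raise ValueError(f"{name} mask is empty")
    return vol.data[m].mean(axis=0)


def nuisance_regress(
    vol: TimeSeriesVolume,
    motion_params: np.ndarray,
    wm_mask: TimeSeriesVolume,
    csf_mask: TimeSeriesVolume,
) -> TimeSeriesVolume:
    """Regress out intercept, WM mean, CSF mean, and the Friston-24 motion
    expansion; returns per-voxel least-squares residuals.

    Raises if the design is rank deficient, naming the collinear columns.
    """
    n_t = vol.n_timepoints
    mp24 = friston24(motion_params)
    if mp24.shape[0] != n_t:
        raise ValueError(
            f"motion trace has {mp24.shape[0]} frames but volume has {n_t}"
        )
    wm = _mask_mean(vol, wm_mask, "WM")
    csf = _mask_mean(vol, csf_mask, "CSF")
    names = (
        ["intercept", "wm", "csf"]
        + [f"mp{i+1}" for i in range(6)]
        + [f"mp{i+1}_lag" for i in range(6)]
        + [f"mp{i+1}_sq" for i in range(6)]
        + [f"mp{i+1}_lag_sq" for i in range(6)]
    )
    X = np.column_stack([np.ones(n_t), wm, csf, mp24])
    # centered rank check so constant-like columns are reported by name
    Xc = X - X.mean(axis=0)
    Xc[:, 0] = 1.0
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        _, r = np.linalg.qr(Xc)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    flat = vol.data.reshape(-1, n_t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return vol.copy_with(data=resid.T.reshape(vol.data.shape))


def smooth(vol: TimeSeriesVolume, fwhm_mm: float = 4.0) -> TimeSeriesVolume:
    """Per-frame isotropic 3-D Gaussian smoothing with the given FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vol.copy_with(data=vol.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.geometry.voxel_size
    # truncate at 6 sigma so the discrete kernel matches the closed-form
    # Gaussian to well below 1e-6
    out = ndimage.gaussian_filter(
        vol.data, sigma=(*sigma_vox, 0.0), mode="constant", truncate=6.0
    )
    return vol.copy_with(data=out)


def run_preprocess(
    vol: TimeSeriesVolume,
    motion_params: np.ndarray,
    wm_mask: TimeSeriesVolume,
    csf_mask: TimeSeriesVolume,
    *,
    discard_n: int = 10,
    fwhm_mm: float = 4.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    fd_threshold: float = 0.2,
    n_back: int = 1,
    n_forward: int = 2,
    head_radius_mm: float = 50.0,
) -> tuple[TimeSeriesVolume, ScrubResult]:
    """Full default chain; see the module docstring for the stage order.

    The motion trace must align with the raw volume (same frame count); the
    initial discard is applied to both. Scrubbed frames are recorded in
    ``timepoint_keep`` (frame deletion, not spike regression) so every
    frame-indexed consumer sees a consistent retained set.
    """
    if motion_params.shape[0] != vol.n_timepoints:
        raise ValueError(
            f"motion trace frames ({motion_params.shape[0]}) != volume frames "
            f"({vol.n_timepoints})"
        )
    logger.info(
        "preprocess: discard=%d smooth=%gmm band=[%g,%g]Hz fd>%g scrub(-%d,+%d)",
        discard_n, fwhm_mm, low_hz, high_hz, fd_threshold, n_back, n_forward,
    )
    vol = discard_initial(vol, discard_n)
    mp = motion_params[discard_n:]
    vol = smooth(vol, fwhm_mm)
    vol = detrend_filter(vol, low_hz, high_hz)
    vol = nuisance_regress(vol, mp, wm_mask, csf_mask)
    scrub = framewise_displacement(mp, head_radius_mm)
    flagged = scrub_flags(scrub.fd, fd_threshold, n_back, n_forward)
    scrub = ScrubResult(fd=scrub.fd, flagged=flagged, mean_fd=scrub.mean_fd)
    vol = vol.copy_with(timepoint_keep=vol.timepoint_keep & ~flagged)
    if vol.n_kept < 2:
        raise ValueError("fewer than 2 frames survive scrubbing")
    return vol, scrub
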