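"""Volumetric containers, NIfTI I/O, and hemisphere labeling.

All stages of the pipeline share three containers defined here:

``GridGeometry``
    the voxel grid (shape, affine) of a volume; world coordinates follow
    the RAS convention, so world x increases toward the subject's right.
``TimeSeriesVolume``
    one subject's 4-D BOLD signal plus a per-timepoint retention mask
    (used by scrubbing) and the repetition time.
``HemisphereMask``
    a brain mask whose in-mask voxels are labeled left / right / midline
    by the *sign of their world x coordinate* (through the affine, not by
    voxel index), so masks with any origin or orientation work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

# integer codes used when a hemisphere label map is exported as NIfTI
LABEL_OUTSIDE = 0
LABEL_LEFT = 1
LABEL_RIGHT = 2
LABEL_MIDLINE = 3


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid: shape, voxel size (mm), and voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular (degenerate voxel-to-world map)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return index @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "GridGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class TimeSeriesVolume:
    """A 4-D signal ``(x, y, z, t)`` with grid geometry and timepoint mask.

    ``timepoint_keep`` marks frames retained after initial-volume discard
    and motion scrubbing; correlations downstream only ever see kept frames.
    """

    data: np.ndarray
    geometry: GridGeometry
    tr_seconds: float = 2.0
    timepoint_keep: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"data must be 3-D or 4-D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.geometry.shape:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} does not match "
                f"geometry {self.geometry.shape}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.timepoint_keep is None:
            self.timepoint_keep = np.ones(self.data.shape[3], dtype=bool)
        else:
            self.timepoint_keep = np.asarray(self.timepoint_keep, dtype=bool)
            if self.timepoint_keep.shape != (self.data.shape[3],):
                raise ValueError("timepoint_keep length must equal number of frames")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def n_kept(self) -> int:
        return int(self.timepoint_keep.sum())

    def copy_with(self, **kwargs) -> "TimeSeriesVolume":
        return replace(self, **kwargs)


@dataclass
class HemisphereMask:
    """Brain mask with per-voxel left/right/midline labels (see module docs)."""

    geometry: GridGeometry
    label: np.ndarray  # int8 codes, same shape as geometry

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int8)
        if self.label.shape != self.geometry.shape:
            raise ValueError("label shape must match geometry shape")
        bad = set(np.unique(self.label)) - {
            LABEL_OUTSIDE,
            LABEL_LEFT,
            LABEL_RIGHT,
            LABEL_MIDLINE,
        }
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    @property
    def in_mask(self) -> np.ndarray:
        return self.label != LABEL_OUTSIDE

    @property
    def n_in_mask(self) -> int:
        return int(self.in_mask.sum())

    def counts(self) -> dict[str, int]:
        return {
            "left": int((self.label == LABEL_LEFT).sum()),
            "right": int((self.label == LABEL_RIGHT).sum()),
            "midline": int((self.label == LABEL_MIDLINE).sum()),
        }

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.label.astype(np.int16), self.geometry.affine)


def load_volume(path, tr_seconds: float | None = None) -> TimeSeriesVolume:
    """Load a 3-D or 4-D NIfTI file; 3-D payloads are promoted to t = 1.

    The repetition time is taken from the header's 4th zoom when present
    and positive, unless ``tr_seconds`` overrides it.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path!r}: expected 3-D or 4-D payload, got {data.ndim}-D")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path!r}: singular affine in header")
    geometry = GridGeometry(shape=data.shape[:3], affine=affine)
    tr = tr_seconds
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if (data.ndim == 4 and len(zooms) > 3 and zooms[3] > 0) else 2.0
    return TimeSeriesVolume(data=data, geometry=geometry, tr_seconds=tr)


def save_volume(vol: TimeSeriesVolume, path) -> None:
    """Write a TimeSeriesVolume as NIfTI (float64, TR recorded in the header)."""
    data = vol.data[..., 0] if vol.n_timepoints == 1 else vol.data
    img = nib.Nifti1Image(data, vol.geometry.affine)
    if data.ndim == 4:
        img.header.set_zooms((*vol.geometry.voxel_size, vol.tr_seconds))
    nib.save(img, str(path))


def build_hemisphere_mask(
    brain_mask: TimeSeriesVolume, midline_policy: str = "exclude"
) -> HemisphereMask:
    """Label every in-mask voxel by the sign of its world x coordinate.

    ``midline_policy`` controls voxels whose centers sit exactly on the
    x = 0 plane: ``"exclude"`` (default) labels them midline so they are
    retained in the brain mask but never enter FC sums as seeds or targets;
    ``"left"``/``"right"`` assigns them to one hemisphere.
    """
    mask3d = brain_mask.data[..., 0] != 0
    if not mask3d.any():
        raise ValueError("brain mask is empty")
    if midline_policy not in ("exclude", "left", "right"):
        raise ValueError(f"unknown midline_policy {midline_policy!r}")
    x_world = brain_mask.geometry.world_coordinates()[..., 0]
    label = np.zeros(brain_mask.geometry.shape, dtype=np.int8)
    label[mask3d & (x_world < 0)] = LABEL_LEFT
    label[mask3d & (x_world > 0)] = LABEL_RIGHT
    midline_code = {
        "exclude": LABEL_MIDLINE,
        "left": LABEL_LEFT,
        "right": LABEL_RIGHT,
    }[midline_policy]
    label[mask3d & (x_world == 0)] = midline_code
    hm = HemisphereMask(geometry=brain_mask.geometry, label=label)
    logger.info("hemisphere mask: %s", hm.counts())
    return hm


def save_map(values: np.ndarray, mask: HemisphereMask, path) -> None:
    """Write a per-voxel map (values over in-mask voxels, C order) as NIfTI.

    Out-of-mask voxels are written as 0. Values are stored as float64, so a
    round trip through :func:`load_volume` is exact.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_in_mask,):
        raise ValueError(
            f"expected {mask.n_in_mask} in-mask values, got shape {values.shape}"
        )
    full = np.zeros(mask.geometry.shape, dtype=np.float64)
    full[mask.in_mask] = values
    nib.save(nib.Nifti1Image(full, mask.geometry.affine), str(path))


def load_map(path, mask: HemisphereMask) -> np.ndarray:
    """Inverse of :func:`save_map`: returns in-mask values in C order."""
    vol = load_volume(path)
    if not vol.geometry.matches(mask.geometry):
        raise ValueError("map geometry does not match mask geometry")
    return vol.data[..., 0][mask.in_mask]
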