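"""The parameter of asymmetry (PAS): inter- minus intra-hemispheric FC.

For every in-mask, non-midline voxel *v* the Pearson correlation with every
other in-mask non-midline voxel is computed over the retained timepoints.
Correlations that are not strictly greater than the threshold (default
r > 0.2; since 0.2 > 0 this also enforces the positive-only rule) are
discarded, the survivors are averaged separately over same-hemisphere
(intra) and opposite-hemisphere (inter) targets, the two means are
Fisher-z transformed, and

    PAS(v) = FC_inter(v) - FC_intra(v)

Positive PAS means the voxel's asymmetry is dominated by interhemispheric
coupling, negative PAS by intra-hemispheric coupling.  A side with zero
surviving correlations is *undefined* (stored as NaN with a zero count and
reported per subject), never silently zero; such voxels are excluded from
group statistics.

The default combination is z(mean r), i.e. the mean surviving correlation
is transformed; ``combine="mean_of_z"`` transforms each surviving r first
and averages the z values instead.

Implementation note: the correlation row of each seed voxel is computed as
a matrix-vector product, one seed at a time, so splitting the seed set into
chunks of any size yields bit-identical results to the unchunked
computation; ``chunk_size`` only bounds the memory of intermediate buffers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes import LABEL_LEFT, LABEL_RIGHT, HemisphereMask, TimeSeriesVolume

logger = logging.getLogger(__name__)


def fisher_z(r):
    """Fisher z transform, ``atanh(r)``; requires ``|r| < 1``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


# mean surviving correlations are clipped just below 1 before the z
# transform so a degenerate perfectly-correlated pair yields a large finite
# value instead of infinity
_R_CLIP = 1.0 - 1e-12


@dataclass
class PASMap:
    """Per-subject voxel-wise FC_inter, FC_intra (z units) and PAS.

    Arrays are 1-D over the mask's eligible (left/right, non-midline)
    voxels in C order; ``eligible`` maps them back onto the grid.
    Undefined sides are NaN with a zero ``n_*_used`` count.
    """

    fc_inter: np.ndarray
    fc_intra: np.ndarray
    pas: np.ndarray
    n_inter_used: np.ndarray
    n_intra_used: np.ndarray
    r_threshold: float
    mask: HemisphereMask
    combine: str = "z_of_mean"
    eligible: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def defined(self) -> np.ndarray:
        """Voxels where both sides have at least one surviving correlation."""
        return (self.n_inter_used > 0) & (self.n_intra_used > 0)

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Embed a per-eligible-voxel vector into the 3-D grid (NaN elsewhere)."""
        full = np.full(self.mask.geometry.shape, np.nan)
        full[self.eligible] = values
        return full


def _eligible_series(
    vol: TimeSeriesVolume, mask: HemisphereMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract standardized kept-timepoint series for eligible voxels.

    Returns (Z, is_left, valid, eligible3d) where ``Z @ Z.T`` gives Pearson
    correlations; constant voxels have ``valid`` False and all-zero rows.
    """
    if not vol.geometry.matches(mask.geometry):
        raise ValueError("volume and mask geometry differ")
    eligible = (mask.label == LABEL_LEFT) | (mask.label == LABEL_RIGHT)
    if not eligible.any():
        raise ValueError("no eligible (non-midline, in-mask) voxels")
    keep = vol.timepoint_keep
    if keep.sum() < 3:
        raise ValueError("need at least 3 retained timepoints for correlation")
    series = vol.data[eligible][:, keep]  # (V, T)
    series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    valid = norms > 0
    Z = np.zeros_like(series)
    Z[valid] = series[valid] / norms[valid, np.newaxis]
    is_left = (mask.label[eligible] == LABEL_LEFT)
    return Z, is_left, valid, eligible


def pas_map(
    vol: TimeSeriesVolume,
    mask: HemisphereMask,
    r_threshold: float = 0.2,
    combine: str = "z_of_mean",
    chunk_size: int | None = None,
) -> PASMap:
    """Compute the PAS map for one subject (see module docstring)."""
    if combine not in ("z_of_mean", "mean_of_z"):
        raise ValueError(f"unknown combine mode {combine!r}")
    Z, is_left, valid, eligible = _eligible_series(vol, mask)
    n_vox = Z.shape[0]
    if chunk_size is None or chunk_size <= 0:
        chunk_size = max(1, min(n_vox, 512))

    sum_inter = np.zeros(n_vox)
    sum_intra = np.zeros(n_vox)
    n_inter = np.zeros(n_vox, dtype=np.int64)
    n_intra = np.zeros(n_vox, dtype=np.int64)

    for start in range(0, n_vox, chunk_size):
        stop = min(start + chunk_size, n_vox)
        for i in range(start, stop):
            if not valid[i]:
                continue
            r = Z @ Z[i]  # correlation of seed i with every voxel
            surv = (r > r_threshold) & valid
            surv[i] = False  # self-correlation excluded
            same = surv & (is_left == is_left[i])
            opp = surv & (is_left != is_left[i])
            vals = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)) if combine == "mean_of_z" else r
            sum_intra[i] = vals.sum(where=same)
            sum_inter[i] = vals.sum(where=opp)
            n_intra[i] = int(same.sum())
            n_inter[i] = int(opp.sum())

    def _fc(s, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        if combine == "z_of_mean":
            mean = np.where(
                np.isnan(mean), np.nan, np.arctanh(np.clip(mean, -_R_CLIP, _R_CLIP))
            )
        return mean

    fc_inter = _fc(sum_inter, n_inter)
    fc_intra = _fc(sum_intra, n_intra)
    pas = fc_inter - fc_intra  # NaN wherever either side is undefined
    n_undef = int(np.isnan(pas).sum())
    if n_undef:
        logger.warning("%d/%d voxels have undefined PAS", n_undef, n_vox)
    return PASMap(
        fc_inter=fc_inter,
        fc_intra=fc_intra,
        pas=pas,
        n_inter_used=n_inter,
        n_intra_used=n_intra,
        r_threshold=r_threshold,
        mask=mask,
        combine=combine,
        eligible=eligible,
    )


def voxel_fc_profile(
    vol: TimeSeriesVolume,
    mask: HemisphereMask,
    seed_voxel: tuple[int, int, int],
    r_threshold: float = 0.2,
) -> tuple[float, float, dict[str, int]]:
    """Mean surviving correlation of one seed voxel per side, on the r scale.

    Returns ``(inter_mean_r, intra_mean_r, counts)``; an undefined side is
    NaN with a zero count. The seed must be in-mask and non-midline, with a
    non-constant series.
    """
    Z, is_left, valid, eligible = _eligible_series(vol, mask)
    flat_eligible = np.flatnonzero(eligible.ravel())
    seed_flat = np.ravel_multi_index(seed_voxel, mask.geometry.shape)
    pos = np.searchsorted(flat_eligible, seed_flat)
    if pos >= flat_eligible.size or flat_eligible[pos] != seed_flat:
        raise ValueError(f"seed voxel {seed_voxel} is not eligible (mask/midline)")
    if not valid[pos]:
        raise ValueError(f"seed voxel {seed_voxel} has a constant time series")
    r = Z @ Z[pos]
    surv = (r > r_threshold) & valid
    surv[pos] = False
    same = surv & (is_left == is_left[pos])
    opp = surv & (is_left != is_left[pos])
    counts = {"n_intra_used": int(same.sum()), "n_inter_used": int(opp.sum())}
    intra = float(r[same].mean()) if counts["n_intra_used"] else float("nan")
    inter = float(r[opp].mean()) if counts["n_inter_used"] else float("nan")
    return inter, intra, counts


def pas_map_bruteforce(
    vol: TimeSeriesVolume,
    mask: HemisphereMask,
    r_threshold: float = 0.2,
    combine: str = "z_of_mean",
) -> PASMap:
    """O(V^2) reference implementation using per-pair ``np.corrcoef``.

    Kept deliberately naive (explicit double loop, no shared standardized
    matrix) as an independent cross-check of :func:`pas_map` on small
    volumes; do not use on more than a few hundred voxels.
    """
    if combine not in ("z_of_mean", "mean_of_z"):
        raise ValueError(f"unknown combine mode {combine!r}")
    eligible = (mask.label == LABEL_LEFT) | (mask.label == LABEL_RIGHT)
    if not eligible.any():
        raise ValueError("no eligible voxels")
    keep = vol.timepoint_keep
    series = vol.data[eligible][:, keep]
    is_left = mask.label[eligible] == LABEL_LEFT
    n_vox = series.shape[0]
    sds = series.std(axis=1)

    fc_inter = np.full(n_vox, np.nan)
    fc_intra = np.full(n_vox, np.nan)
    n_inter = np.zeros(n_vox, dtype=np.int64)
    n_intra = np.zeros(n_vox, dtype=np.int64)
    for i in range(n_vox):
        if sds[i] == 0:
            continue
        same_r, opp_r = [], []
        for j in range(n_vox):
            if j == i or sds[j] == 0:
                continue
            r = float(np.corrcoef(series[i], series[j])[0, 1])
            if not (r > r_threshold and r > 0):
                continue
            (same_r if is_left[j] == is_left[i] else opp_r).append(r)
        if combine == "mean_of_z":
            same_r = [float(np.arctanh(min(max(r, -_R_CLIP), _R_CLIP))) for r in same_r]
            opp_r = [float(np.arctanh(min(max(r, -_R_CLIP), _R_CLIP))) for r in opp_r]
        n_intra[i], n_inter[i] = len(same_r), len(opp_r)
        if same_r:
            m = float(np.mean(same_r))
            fc_intra[i] = np.arctanh(min(m, _R_CLIP)) if combine == "z_of_mean" else m
        if opp_r:
            m = float(np.mean(opp_r))
            fc_inter[i] = np.arctanh(min(m, _R_CLIP)) if combine == "z_of_mean" else m
    return PASMap(
        fc_inter=fc_inter,
        fc_intra=fc_intra,
        pas=fc_inter - fc_intra,
        n_inter_used=n_inter,
        n_intra_used=n_intra,
        r_threshold=r_threshold,
        mask=mask,
        combine=combine,
        eligible=eligible,
    )
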