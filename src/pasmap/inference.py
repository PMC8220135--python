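"""Group-level inference on PAS maps.

Voxel-wise one-sample and covariate-adjusted two-sample t-tests, followed
by cluster-extent correction using Gaussian-random-field (GRF) theory:
map smoothness (FWHM) is estimated from the standardized model residuals,
suprathreshold clusters are formed at the voxel threshold (26-connectivity
by default, each sign separately), and each cluster receives a corrected
p-value from the expected-Euler-characteristic approximation for the
excursion set of a 3-D Gaussian field.  A permutation-based correction is
provided as an independent cross-check: GRF is an asymptotic approximation
whose accuracy on desk-scale grids is limited.

Subjects with undefined PAS at a voxel are dropped listwise at that voxel;
by default a voxel is analyzed only when every subject is defined there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .pas import PASMap
from .volumes import HemisphereMask

logger = logging.getLogger(__name__)

_T_CAP = 1e6  # zero-variance voxels report a capped t with a warning


@dataclass
class StatMap:
    """A voxel-wise t map over the eligible voxels of a hemisphere mask."""

    t: np.ndarray  # 1-D over eligible voxels; NaN where not analyzed
    df: int
    contrast: str
    covariates: list[str]
    mask: HemisphereMask
    eligible: np.ndarray  # 3-D bool
    analyzed: np.ndarray  # 1-D bool over eligible voxels
    residuals: np.ndarray | None = None  # (n_subjects, n_eligible)

    def t_grid(self) -> np.ndarray:
        full = np.full(self.mask.geometry.shape, np.nan)
        full[self.eligible] = self.t
        return full


@dataclass
class ClusterTable:
    """Suprathreshold clusters surviving cluster-level correction.

    ``table`` columns: location_label, x, y, z (world mm of the peak
    |t| voxel), n_voxels, peak_t, cluster_p — sorted by |peak_t|
    descending. ``label_grid`` assigns each voxel its cluster's 1-based row
    index (0 = background) for feature extraction.
    """

    table: pd.DataFrame
    label_grid: np.ndarray
    mask: HemisphereMask
    voxel_p: float
    cluster_p: float
    smoothness_fwhm_vox: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def stack_pas_maps(maps: list[PASMap]) -> tuple[np.ndarray, PASMap]:
    """Stack per-subject PAS vectors into (n_subjects, n_voxels); verifies a
    shared mask geometry."""
    if not maps:
        raise ValueError("no PAS maps given")
    ref = maps[0]
    for m in maps[1:]:
        if not m.mask.geometry.matches(ref.mask.geometry):
            raise ValueError("PAS maps have mismatched geometry")
        if not np.array_equal(m.eligible, ref.eligible):
            raise ValueError("PAS maps have mismatched eligible voxel sets")
    return np.vstack([m.pas for m in maps]), ref


def _finalize_t(t: np.ndarray, zero_var: np.ndarray) -> np.ndarray:
    if zero_var.any():
        logger.warning(
            "%d voxels have zero residual variance; t capped at ±%.0e",
            int(zero_var.sum()), _T_CAP,
        )
    return t


def one_sample_t(maps: list[PASMap] | np.ndarray, mask_ref: PASMap | None = None) -> StatMap:
    """Per-voxel one-sample t of mean PAS against 0 (df = n - 1)."""
    if isinstance(maps, np.ndarray):
        stack, ref = maps, mask_ref
        if ref is None:
            raise ValueError("mask_ref required when passing a raw stack")
    else:
        stack, ref = stack_pas_maps(maps)
    n = stack.shape[0]
    if n < 3:
        raise ValueError("one-sample t needs at least 3 subjects")
    analyzed = ~np.isnan(stack).any(axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = analyzed & (sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero_var, np.sign(mean) * _T_CAP, t)
    t = _finalize_t(t, zero_var)
    t[~analyzed] = np.nan
    resid = stack - mean
    return StatMap(
        t=t, df=n - 1, contrast="mean PAS vs 0", covariates=[],
        mask=ref.mask, eligible=ref.eligible, analyzed=analyzed, residuals=resid,
    )


def two_sample_t_adjusted(
    maps: list[PASMap] | np.ndarray,
    groups,
    covariates: pd.DataFrame | None = None,
    mask_ref: PASMap | None = None,
) -> StatMap:
    """Per-voxel t on the group coefficient of the GLM
    ``pas ~ intercept + group + covariates`` (patients minus controls).

    ``groups`` is a per-subject label sequence; "patients" are coded 1.
    ``covariates`` (e.g. age, mean FD) are centered before fitting.
    """
    if isinstance(maps, np.ndarray):
        stack, ref = maps, mask_ref
        if ref is None:
            raise ValueError("mask_ref required when passing a raw stack")
    else:
        stack, ref = stack_pas_maps(maps)
    groups = np.asarray(groups)
    n = stack.shape[0]
    if groups.shape[0] != n:
        raise ValueError("groups length must match number of subjects")
    if groups.dtype.kind in "USO":  # string labels (incl. pandas object dtype)
        g = (groups == "patients").astype(float)
    else:
        g = groups.astype(float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError("both groups need at least 3 subjects")
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    cov_names: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            v = covariates[name].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(name)
            cov_names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design {names} (rank {rank} < {X.shape[1]})")
    df = n - X.shape[1]
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    analyzed = ~np.isnan(stack).any(axis=0)
    Y = np.where(analyzed, stack, 0.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    zero_var = analyzed & (se == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    t = np.where(zero_var, np.sign(beta[1]) * _T_CAP, t)
    t = _finalize_t(t, zero_var)
    t[~analyzed] = np.nan
    resid[:, ~analyzed] = np.nan
    return StatMap(
        t=t, df=df, contrast="patients - controls", covariates=cov_names,
        mask=ref.mask, eligible=ref.eligible, analyzed=analyzed, residuals=resid,
    )


def estimate_smoothness_fwhm(
    residuals: np.ndarray, eligible: np.ndarray, analyzed: np.ndarray
) -> np.ndarray:
    """Per-axis smoothness (FWHM, voxel units) from standardized residuals.

    Residual maps are normalized to unit sum-of-squares per voxel; the
    variance of their spatial first differences estimates the roughness
    ``lambda_a`` per axis, and ``FWHM_a = sqrt(4 ln 2 / lambda_a)``.
    """
    shape = eligible.shape
    ok3 = np.zeros(shape, dtype=bool)
    ok3[eligible] = analyzed
    ssq = np.nan_to_num((residuals**2).sum(axis=0))
    good = analyzed & (ssq > 0)
    u = np.zeros_like(residuals)
    u[:, good] = residuals[:, good] / np.sqrt(ssq[good])
    fwhm = np.zeros(3)
    for axis in range(3):
        u3 = np.zeros((residuals.shape[0], *shape))
        u3[:, eligible] = u
        valid3 = np.zeros(shape, dtype=bool)
        valid3[eligible] = good
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        pair_ok = valid3[tuple(sl_lo)] & valid3[tuple(sl_hi)]
        if not pair_ok.any():
            raise ValueError(f"cannot estimate smoothness along axis {axis}: no voxel pairs")
        diffs = u3[(slice(None), *sl_hi)] - u3[(slice(None), *sl_lo)]
        lam = (diffs[:, pair_ok] ** 2).sum(axis=0).mean()
        if not np.isfinite(lam) or lam <= 0:
            raise ValueError(
                f"degenerate smoothness estimate along axis {axis} (lambda={lam});"
                " residuals may be constant"
            )
        fwhm[axis] = np.sqrt(4.0 * np.log(2.0) / lam)
    return fwhm


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18, or 26")
    return ndimage.generate_binary_structure(3, order)


def _ec_density_3d(u: float) -> float:
    """3-D EC density of a unit Gaussian field at threshold u, per resel."""
    return (4 * np.log(2.0)) ** 1.5 * (2 * np.pi) ** -2 * (u**2 - 1) * np.exp(-(u**2) / 2)


def grf_cluster_correct(
    stat: StatMap,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    residuals: np.ndarray | None = None,
    connectivity: int = 26,
    two_sided: bool = True,
) -> ClusterTable:
    """GRF cluster-extent correction of a t map.

    The voxel threshold is two-sided by default (each sign is thresholded
    at ``voxel_p / 2`` one-tailed and clustered separately; the expected
    cluster count is doubled accordingly in the corrected p).  Cluster
    corrected p uses the standard excursion-set approximation:
    ``P = 1 - exp(-E[m] * exp(-beta * k_resels^(2/3)))``.
    """
    residuals = stat.residuals if residuals is None else residuals
    if residuals is None:
        raise ValueError("residual maps are required for smoothness estimation")
    fwhm = estimate_smoothness_fwhm(residuals, stat.eligible, stat.analyzed)
    n_analyzed = int(stat.analyzed.sum())
    resels = n_analyzed / float(np.prod(fwhm))
    p_tail = voxel_p / 2 if two_sided else voxel_p
    t_thr = stats.t.isf(p_tail, stat.df)
    u = stats.norm.isf(p_tail)  # Gaussianized threshold
    if u <= 1:
        raise ValueError(f"voxel threshold too lenient for GRF (z = {u:.2f} <= 1)")
    em_one = resels * _ec_density_3d(u)
    em_total = (2 if two_sided else 1) * em_one
    exp_vox_resels = resels * stats.norm.sf(u)
    if em_one <= 0 or exp_vox_resels <= 0:
        raise ValueError("degenerate GRF expectations; check smoothness/threshold")
    exp_cluster_resels = exp_vox_resels / em_one
    beta = (math.gamma(2.5) / exp_cluster_resels) ** (2.0 / 3.0)

    t3 = stat.t_grid()
    structure = _connectivity_structure(connectivity)
    label_grid = np.zeros(stat.mask.geometry.shape, dtype=np.int32)
    rows = []
    signs = [1, -1] if two_sided else [1]
    clusters = []
    for sign in signs:
        supra = np.nan_to_num(sign * t3, nan=-np.inf) > t_thr
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = labels == lab
            k = int(vox.sum())
            k_resels = k / float(np.prod(fwhm))
            p_size = np.exp(-beta * k_resels ** (2.0 / 3.0))
            p_corr = float(1.0 - np.exp(-em_total * p_size))
            tvals = t3[vox]
            peak_pos = np.argwhere(vox)[np.argmax(np.abs(tvals))]
            peak_t = float(tvals[np.argmax(np.abs(tvals))])
            clusters.append((vox, k, peak_t, peak_pos, p_corr))
    clusters = [c for c in clusters if c[4] < cluster_p]
    clusters.sort(key=lambda c: -abs(c[2]))
    for i, (vox, k, peak_t, peak_pos, p_corr) in enumerate(clusters, start=1):
        label_grid[vox] = i
        world = stat.mask.geometry.voxel_to_world(peak_pos)
        rows.append(
            {
                "location_label": f"cluster_{i}",
                "x": float(world[0]),
                "y": float(world[1]),
                "z": float(world[2]),
                "n_voxels": k,
                "peak_t": peak_t,
                "cluster_p": p_corr,
            }
        )
    table = pd.DataFrame(
        rows, columns=["location_label", "x", "y", "z", "n_voxels", "peak_t", "cluster_p"]
    )
    logger.info(
        "GRF: FWHM(vox)=%s resels=%.1f E[m]=%.4f -> %d surviving clusters",
        np.round(fwhm, 2), resels, em_total, len(table),
    )
    return ClusterTable(
        table=table, label_grid=label_grid, mask=stat.mask,
        voxel_p=voxel_p, cluster_p=cluster_p, smoothness_fwhm_vox=fwhm,
    )


def permutation_cluster_correct(
    maps: list[PASMap] | np.ndarray,
    groups,
    covariates: pd.DataFrame | None = None,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 26,
    seed: int = 0,
    mask_ref: PASMap | None = None,
) -> ClusterTable:
    """Cluster correction by group-label permutation (max cluster extent).

    An independent, assumption-light alternative to GRF: the null
    distribution of the maximum suprathreshold cluster size (over both
    signs) is built by relabeling subjects; each observed cluster's
    corrected p is its rank against that null.
    """
    if isinstance(maps, np.ndarray):
        stack, ref = maps, mask_ref
    else:
        stack, ref = stack_pas_maps(maps)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    structure = _connectivity_structure(connectivity)

    def max_cluster_size(stat: StatMap) -> int:
        t3 = stat.t_grid()
        t_thr = stats.t.isf(voxel_p / 2, stat.df)
        best = 0
        for sign in (1, -1):
            supra = np.nan_to_num(sign * t3, nan=-np.inf) > t_thr
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        return best

    observed = two_sample_t_adjusted(stack, groups, covariates, mask_ref=ref)
    t_thr = stats.t.isf(voxel_p / 2, observed.df)
    null_max = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(len(groups))
        sm = two_sample_t_adjusted(
            stack, groups[perm],
            covariates.iloc[perm].reset_index(drop=True) if covariates is not None else None,
            mask_ref=ref,
        )
        null_max[b] = max_cluster_size(sm)

    t3 = observed.t_grid()
    label_grid = np.zeros(ref.mask.geometry.shape, dtype=np.int32)
    clusters = []
    for sign in (1, -1):
        supra = np.nan_to_num(sign * t3, nan=-np.inf) > t_thr
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = labels == lab
            k = int(vox.sum())
            p_corr = float((1 + (null_max >= k).sum()) / (n_perm + 1))
            tvals = t3[vox]
            peak_pos = np.argwhere(vox)[np.argmax(np.abs(tvals))]
            clusters.append((vox, k, float(tvals[np.argmax(np.abs(tvals))]), peak_pos, p_corr))
    clusters = [c for c in clusters if c[4] < cluster_p]
    clusters.sort(key=lambda c: -abs(c[2]))
    rows = []
    for i, (vox, k, peak_t, peak_pos, p_corr) in enumerate(clusters, start=1):
        label_grid[vox] = i
        world = ref.mask.geometry.voxel_to_world(peak_pos)
        rows.append(
            {
                "location_label": f"cluster_{i}",
                "x": float(world[0]), "y": float(world[1]), "z": float(world[2]),
                "n_voxels": k, "peak_t": peak_t, "cluster_p": p_corr,
            }
        )
    table = pd.DataFrame(
        rows, columns=["location_label", "x", "y", "z", "n_voxels", "peak_t", "cluster_p"]
    )
    return ClusterTable(
        table=table, label_grid=label_grid, mask=ref.mask,
        voxel_p=voxel_p, cluster_p=cluster_p,
    )


def extract_cluster_means(
    maps: list[PASMap] | np.ndarray,
    clusters: ClusterTable,
    mask_ref: PASMap | None = None,
) -> pd.DataFrame:
    """Per-subject mean PAS within each surviving cluster.

    Returns an (n_subjects x n_clusters) DataFrame whose columns are the
    cluster location labels.
    """
    if isinstance(maps, np.ndarray):
        stack, ref = maps, mask_ref
    else:
        stack, ref = stack_pas_maps(maps)
    if len(clusters) == 0:
        raise ValueError("cluster table is empty")
    eligible3 = ref.eligible
    out = {}
    for i, row in clusters.table.iterrows():
        lab = i + 1
        vox = clusters.label_grid == lab
        if not (vox & eligible3).sum() == vox.sum():
            raise ValueError(f"cluster {row.location_label} extends outside the analysis mask")
        sel = vox[eligible3]
        out[row.location_label] = stack[:, sel].mean(axis=1)
    return pd.DataFrame(out)
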