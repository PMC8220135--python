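"""Synthetic resting-state cohort generator.

Emulates the data structure the PAS analysis assumes — two groups of
subjects, each with a 4-D BOLD series on a common 3 mm grid, a 6-column
rigid-body motion trace with occasional spikes, and clinical scores — with
*known* planted ground truth, so every downstream stage is testable without
external data.

Signal model (per voxel v in hemisphere H, unit-variance construction)::

    x_v(t) = sqrt(c_g) g(t) + a_v n_H(t) + w_v n_H'(t) + s_v e_v(t)

where g is a global bilateral (homotopic) latent signal, n_L / n_R are
per-hemisphere network latents, and e_v is white noise, spatially smoothed
and re-standardized. All latents are band-limited to the analysis band so
they survive the band-pass filter. With no planted effects,
``a_v = sqrt(c_h)`` everywhere, giving baseline pairwise correlations

    corr(v, w)  =  base_inter_r            (opposite hemispheres, = c_g)
    corr(v, w)  =  base_intra_r            (same hemisphere, = c_g + c_h)

Planted effects perturb the weights of region voxels in one group:

``raise_intra`` with strength s
    adds ``s / sqrt(c_h)`` to the own-hemisphere weight, raising the
    region's same-hemisphere correlations by s (opposite-hemisphere
    correlations untouched) — which *lowers* PAS there;
``raise_inter`` with strength s
    gives region voxels weight ``s / sqrt(c_h)`` on the *contralateral*
    hemisphere latent, raising their opposite-hemisphere correlations by s
    — which *raises* PAS.

The per-voxel noise variance is chosen to keep total variance at 1, so the
stated correlations are exact in the construction (sample correlations
fluctuate with 1/sqrt(T)); an infeasible strength (non-positive residual
noise variance, i.e. an implied correlation structure that is not positive
semi-definite) raises at generation time naming the offending effect.
``noise_sd`` rescales only the noise term; at its default of 1 the baseline
correlations above hold exactly.

Clinical scores are drawn per group from a normal model truncated at 0
(severity scales are nonnegative; the truncation bias is negligible for
the default profile, where means sit several SDs above 0 for patients).
The default clinical profile matches a medication-free OCD cohort versus
matched healthy controls (Y-BOCS total/obsessive/compulsive, HAMD, HAMA,
age, education group means and SDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import FWHM_TO_SIGMA
from .volumes import (
    GridGeometry,
    HemisphereMask,
    TimeSeriesVolume,
    build_hemisphere_mask,
)

#: Default per-group clinical model: score -> group -> (mean, sd).
#: Matches the study-cohort profile the generator emulates.
DEFAULT_CLINICAL_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"patients": (27.28, 8.16), "controls": (27.18, 8.33)},
    "education": {"patients": (13.40, 2.87), "controls": (13.74, 3.03)},
    "ybocs_total": {"patients": (24.90, 5.73), "controls": (1.13, 0.88)},
    "ybocs_obsessive": {"patients": (12.85, 4.25), "controls": (0.37, 0.49)},
    "ybocs_compulsive": {"patients": (12.05, 4.62), "controls": (0.74, 0.72)},
    "hamd": {"patients": (8.05, 4.40), "controls": (1.45, 0.95)},
    "hama": {"patients": (10.83, 6.55), "controls": (1.16, 1.00)},
}

GROUPS = ("patients", "controls")


def default_grid(shape: tuple[int, int, int] = (20, 24, 20), voxel_mm: float = 3.0) -> GridGeometry:
    """Desk-scale grid at nominal 3 mm, centered so no voxel sits at x = 0
    when the first axis has even length (RAS orientation)."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return GridGeometry(shape=tuple(shape), affine=affine)


def ellipsoid_mask(grid: GridGeometry, scale: float = 0.9) -> TimeSeriesVolume:
    """Binary two-hemisphere brain mask: an axis-aligned ellipsoid filling
    ``scale`` of each half-extent of the grid."""
    world = grid.world_coordinates()
    half = grid.voxel_size * np.asarray(grid.shape) / 2.0
    rel = world / (half * scale)
    mask = (rel**2).sum(axis=-1) <= 1.0
    return TimeSeriesVolume(data=mask.astype(float), geometry=grid)


def toy_tissue_masks(grid: GridGeometry) -> tuple[TimeSeriesVolume, TimeSeriesVolume]:
    """Toy WM and CSF masks: a central deep-white ellipsoid (WM) and two
    ventricle-like balls on the midline (CSF), all well inside the default
    brain mask.  These compartments carry tissue nuisance signals in the
    generator and are excluded from the PAS analysis mask."""
    world = grid.world_coordinates()
    half = grid.voxel_size * np.asarray(grid.shape) / 2.0
    rel = world / half
    wm = (rel**2).sum(axis=-1) <= 0.30**2
    csf = np.zeros(grid.shape, dtype=bool)
    for cy in (0.5, -0.5):
        csf |= (((rel - np.array([0.0, cy, 0.0])) ** 2).sum(axis=-1)) <= 0.25**2
    csf &= ~wm
    return (
        TimeSeriesVolume(data=wm.astype(float), geometry=grid),
        TimeSeriesVolume(data=csf.astype(float), geometry=grid),
    )


def sphere_region(grid: GridGeometry, center_mm, radius_mm: float) -> np.ndarray:
    """Flat (raveled, C-order) indices of voxels within ``radius_mm`` of a
    world-mm center — convenience for defining effect regions."""
    world = grid.world_coordinates().reshape(-1, 3)
    d2 = ((world - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    idx = np.flatnonzero(d2 <= radius_mm**2)
    if idx.size == 0:
        raise ValueError(f"no voxels within {radius_mm} mm of {center_mm}")
    return idx


@dataclass
class EffectSpec:
    """A planted group effect: a voxel region, a mode, and a strength.

    ``region`` holds flat C-order voxel indices into the grid; ``strength``
    is the correlation increment in [0, 1) applied as described in the
    module docstring; ``group`` selects who receives it.
    """

    region: np.ndarray
    mode: str  # "raise_intra" | "raise_inter"
    strength: float
    group: str = "patients"  # "patients" | "controls" | "both"
    name: str = ""

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=np.int64)
        if self.mode not in ("raise_intra", "raise_inter"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if not (0 <= self.strength < 1):
            raise ValueError("strength must be in [0, 1)")
        if self.group not in ("patients", "controls", "both"):
            raise ValueError(f"unknown group {self.group!r}")

    def applies_to(self, group: str) -> bool:
        return self.group == "both" or self.group == group


@dataclass
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_patients: int = 40
    n_controls: int = 38
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    grid: GridGeometry = dc_field(default_factory=default_grid)
    noise_sd: float = 1.0
    smoothness_fwhm_mm: float = 4.0
    base_inter_r: float = 0.30
    base_intra_r: float = 0.35
    signal_band_hz: tuple[float, float] = (0.01, 0.08)
    effects: list[EffectSpec] = dc_field(default_factory=list)
    motion_spike_rate: float = 0.001
    motion_walk_sd_mm: float = 0.01
    motion_walk_sd_rad: float = 1e-4
    clinical_model: dict = dc_field(default_factory=lambda: DEFAULT_CLINICAL_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0 or self.noise_sd <= 0:
            raise ValueError("tr_seconds and noise_sd must be positive")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness_fwhm_mm must be nonnegative")
        if not (0 < self.base_inter_r < self.base_intra_r < 1):
            raise ValueError("need 0 < base_inter_r < base_intra_r < 1")
        if not (0 <= self.motion_spike_rate < 1):
            raise ValueError("motion_spike_rate must be a probability")


def cohort_mask(spec: CohortSpec) -> HemisphereMask:
    """The hemisphere-labeled analysis mask: the brain ellipsoid minus the
    toy WM/CSF compartments (tissue voxels carry nuisance signals, not the
    neural latents, and are excluded from PAS)."""
    brain = ellipsoid_mask(spec.grid).data[..., 0] != 0
    wm, csf = toy_tissue_masks(spec.grid)
    gray = brain & (wm.data[..., 0] == 0) & (csf.data[..., 0] == 0)
    return build_hemisphere_mask(
        TimeSeriesVolume(data=gray.astype(float), geometry=spec.grid)
    )


def _band_limited_latents(rng, n_sig, n_t, tr, band) -> np.ndarray:
    """Unit-variance, zero-mean latent signals band-limited to ``band``."""
    low, high = band
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if keep.sum() < 2:
        raise ValueError(
            f"band {band} Hz retains fewer than 2 frequency bins at "
            f"n_t={n_t}, TR={tr}s"
        )
    x = rng.standard_normal((n_sig, n_t))
    spec_f = np.fft.rfft(x, axis=1)
    spec_f[:, ~keep] = 0.0
    x = np.fft.irfft(spec_f, n=n_t, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return x / sd


def _voxel_weights(
    spec: CohortSpec, mask: HemisphereMask, group: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-eligible-voxel weights (own-hemi, opposite-hemi, noise-sd) and the
    left-hemisphere indicator; raises on an infeasible effect."""
    from .volumes import LABEL_LEFT, LABEL_RIGHT

    eligible = (mask.label == LABEL_LEFT) | (mask.label == LABEL_RIGHT)
    flat_eligible = np.flatnonzero(eligible.ravel())
    is_left = mask.label.ravel()[flat_eligible] == LABEL_LEFT
    c_g = spec.base_inter_r
    c_h = spec.base_intra_r - spec.base_inter_r
    own = np.full(flat_eligible.size, np.sqrt(c_h))
    opp = np.zeros(flat_eligible.size)
    pos_of = {flat: i for i, flat in enumerate(flat_eligible)}
    for k, eff in enumerate(spec.effects):
        if not eff.applies_to(group):
            continue
        idx = [pos_of[f] for f in eff.region if f in pos_of]
        if not idx:
            raise ValueError(f"effect {eff.name or k}: region has no eligible voxels")
        idx = np.asarray(idx)
        if eff.mode == "raise_intra":
            if len(set(is_left[idx])) > 1:
                raise ValueError(
                    f"effect {eff.name or k}: raise_intra region must lie in one hemisphere"
                )
            own[idx] += eff.strength / np.sqrt(c_h)
        else:
            opp[idx] += eff.strength / np.sqrt(c_h)
    noise_var = 1.0 - c_g - own**2 - opp**2
    if np.any(noise_var <= 0):
        bad = int(np.argmin(noise_var))
        raise ValueError(
            "implied correlation structure is not positive semi-definite: "
            f"residual noise variance {noise_var[bad]:.4f} <= 0 at eligible voxel "
            f"{bad}; reduce effect strengths "
            f"({[e.name or i for i, e in enumerate(spec.effects)]})"
        )
    return own, opp, np.sqrt(noise_var), is_left


def _motion_trace(rng, spec: CohortSpec) -> np.ndarray:
    """Slow 6-parameter random walk plus occasional level-shift spikes."""
    n_t = spec.n_timepoints
    steps = rng.standard_normal((n_t, 6))
    steps[:, :3] *= spec.motion_walk_sd_mm
    steps[:, 3:] *= spec.motion_walk_sd_rad
    steps[0] = 0.0
    spikes = rng.random(n_t) < spec.motion_spike_rate
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        amp = rng.uniform(0.25, 0.8) * rng.choice([-1.0, 1.0])
        steps[i, axis] += amp  # level shift: one FD exceedance per spike
    return np.cumsum(steps, axis=0)


def _clinical_record(rng, spec: CohortSpec, group: str) -> dict[str, float]:
    rec = {}
    for score, by_group in spec.clinical_model.items():
        mean, sd = by_group[group]
        rec[score] = float(max(0.0, rng.normal(mean, sd)))  # scores are nonnegative
    return rec


def generate_subject(
    spec: CohortSpec, group: str, subject_seed: int
) -> tuple[TimeSeriesVolume, np.ndarray, dict[str, float]]:
    """Generate one subject: (4-D volume, motion trace, clinical record).

    Deterministic in ``(spec, group, subject_seed)``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(subject_seed)
    mask = cohort_mask(spec)
    own, opp, noise_sd_v, is_left = _voxel_weights(spec, mask, group)
    n_t = spec.n_timepoints
    # latents: global bilateral g, left network, right network, plus
    # tissue nuisance signals for the WM/CSF compartments
    g, n_left, n_right, wm_latent, csf_latent = _band_limited_latents(
        rng, 5, n_t, spec.tr_seconds, spec.signal_band_hz
    )
    # spatially smoothed, per-voxel re-standardized white noise
    noise = rng.standard_normal((*spec.grid.shape, n_t))
    if spec.smoothness_fwhm_mm > 0:
        sigma_vox = spec.smoothness_fwhm_mm * FWHM_TO_SIGMA / spec.grid.voxel_size
        noise = ndimage.gaussian_filter(noise, sigma=(*sigma_vox, 0.0), mode="constant")
        noise -= noise.mean(axis=3, keepdims=True)
        sd = noise.std(axis=3, keepdims=True)
        sd[sd == 0] = 1.0
        noise /= sd

    from .volumes import LABEL_LEFT, LABEL_RIGHT

    eligible = (mask.label == LABEL_LEFT) | (mask.label == LABEL_RIGHT)
    c_g = spec.base_inter_r
    own_latent = np.where(is_left[:, None], n_left, n_right)
    opp_latent = np.where(is_left[:, None], n_right, n_left)
    series = (
        np.sqrt(c_g) * g[None, :]
        + own[:, None] * own_latent
        + opp[:, None] * opp_latent
        + (spec.noise_sd * noise_sd_v)[:, None] * noise[eligible]
    )
    data = np.zeros((*spec.grid.shape, n_t))
    data[eligible] = series
    # tissue compartments: a shared nuisance latent plus noise, carrying no
    # neural signal (what WM/CSF regression is meant to remove)
    wm, csf = toy_tissue_masks(spec.grid)
    for tissue_mask, latent in ((wm.data[..., 0] != 0, wm_latent),
                                (csf.data[..., 0] != 0, csf_latent)):
        if tissue_mask.any():
            data[tissue_mask] = (
                0.8 * latent[None, :]
                + 0.6 * spec.noise_sd * noise[tissue_mask]
            )
    vol = TimeSeriesVolume(data=data, geometry=spec.grid, tr_seconds=spec.tr_seconds)
    motion = _motion_trace(rng, spec)
    clinical = _clinical_record(rng, spec, group)
    return vol, motion, clinical


@dataclass
class Subject:
    subject_id: str
    group: str
    volume: TimeSeriesVolume
    motion: np.ndarray
    clinical: dict[str, float]


def subject_seeds(spec: CohortSpec) -> dict[str, int]:
    """Per-subject seeds derived deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"patient_{i+1:03d}" for i in range(spec.n_patients)] + [
        f"control_{i+1:03d}" for i in range(spec.n_controls)
    ]
    seeds = rng.integers(0, 2**31 - 1, size=len(ids))
    return dict(zip(ids, (int(s) for s in seeds)))


def generate_cohort(
    spec: CohortSpec, out_dir=None
) -> tuple[list[Subject], pd.DataFrame]:
    """Generate the full cohort; optionally write volumes/motion/manifest.

    Returns ``(subjects, manifest)``. When ``out_dir`` is given, each
    subject's volume is written as NIfTI (float32), its motion trace as a
    6-column text file, the brain/WM/CSF masks as NIfTI, and the manifest
    as ``manifest.tsv`` with per-subject paths.
    """
    import pathlib

    from .volumes import save_volume

    seeds = subject_seeds(spec)
    subjects: list[Subject] = []
    rows = []
    out = pathlib.Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        mask = cohort_mask(spec)
        wm, csf = toy_tissue_masks(spec.grid)
        # the analysis mask (brain minus tissue compartments), suitable for
        # PAS computation via `pasmap compute --mask`
        save_volume(
            TimeSeriesVolume(data=mask.in_mask.astype(float), geometry=spec.grid),
            out / "brain_mask.nii",
        )
        save_volume(wm, out / "wm_mask.nii")
        save_volume(csf, out / "csf_mask.nii")
    for sid, sseed in seeds.items():
        group = "patients" if sid.startswith("patient") else "controls"
        vol, motion, clinical = generate_subject(spec, group, sseed)
        subjects.append(Subject(sid, group, vol, motion, clinical))
        row = {"subject_id": sid, "group": group, "seed": sseed, **clinical}
        if out is not None:
            vol_path = out / f"{sid}_bold.nii"
            img_vol = vol.copy_with(data=vol.data.astype(np.float32))
            save_volume(img_vol, vol_path)
            motion_path = out / f"{sid}_motion.txt"
            np.savetxt(motion_path, motion, fmt="%.8f")
            row["bold_path"] = str(vol_path)
            row["motion_path"] = str(motion_path)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return subjects, manifest
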