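"""End-to-end orchestration: simulate -> preprocess -> PAS -> group stats ->
correlations -> classification, from one :class:`~pasmap.config.RunConfig`.

Every enabled stage writes its outputs plus a provenance sidecar (config
hash, package version, seed) into the run directory; reruns with the same
config are bit-identical for all deterministic stages. Stage dependencies
are checked up front so a disabled prerequisite fails with a clear error
instead of a missing file deep in a later stage.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    COARSE_C_GRID,
    COARSE_GAMMA_GRID,
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    classify_regions,
)
from .clinical import correlation_results_frame, group_summary_table, pearson_with_bonferroni
from .config import RunConfig
from .inference import (
    extract_cluster_means,
    grf_cluster_correct,
    one_sample_t,
    permutation_cluster_correct,
    two_sample_t_adjusted,
)
from .pas import pas_map
from .preprocess import run_preprocess
from .synthetic import (
    CohortSpec,
    EffectSpec,
    cohort_mask,
    default_grid,
    generate_cohort,
    sphere_region,
    toy_tissue_masks,
)
from .volumes import save_map

logger = logging.getLogger(__name__)

_STAGE_DEPS = {
    "preprocess": ["simulate"],
    "pas": ["simulate", "preprocess"],
    "group": ["pas"],
    "correlate": ["group"],
    "classify": ["group"],
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def cohort_spec_from_config(cfg: RunConfig) -> CohortSpec:
    grid = default_grid(tuple(cfg.simulate.grid_shape), cfg.simulate.voxel_mm)
    effects = [
        EffectSpec(
            region=sphere_region(grid, e.center_mm, e.radius_mm),
            mode=e.mode,
            strength=e.strength,
            group=e.group,
            name=e.name or f"effect_{i}",
        )
        for i, e in enumerate(cfg.simulate.effects)
    ]
    return CohortSpec(
        n_patients=cfg.simulate.n_patients,
        n_controls=cfg.simulate.n_controls,
        n_timepoints=cfg.simulate.n_timepoints,
        tr_seconds=cfg.simulate.tr_seconds,
        grid=grid,
        noise_sd=cfg.simulate.noise_sd,
        smoothness_fwhm_mm=cfg.simulate.smoothness_fwhm_mm,
        base_inter_r=cfg.simulate.base_inter_r,
        base_intra_r=cfg.simulate.base_intra_r,
        effects=effects,
        motion_spike_rate=cfg.simulate.motion_spike_rate,
        seed=cfg.seed,
    )


def _check_stage_deps(cfg: RunConfig) -> None:
    enabled = cfg.stages.model_dump()
    for stage, deps in _STAGE_DEPS.items():
        if enabled.get(stage):
            for dep in deps:
                if not enabled.get(dep):
                    raise PipelineError(
                        f"stage '{stage}' requires stage '{dep}', which is disabled"
                    )


def run_pipeline(cfg: RunConfig, out_dir) -> pathlib.Path:
    """Run all enabled stages; returns the run directory."""
    _check_stage_deps(cfg)
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": cfg.config_hash(),
        "package_version": __version__,
        "seed": cfg.seed,
    }
    (out / "config.yaml").write_text(cfg.to_yaml())
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    stage = "simulate"
    try:
        spec = cohort_spec_from_config(cfg)
        mask = cohort_mask(spec)
        subjects, manifest = generate_cohort(spec)
        logger.info("simulate: %d subjects on grid %s", len(subjects), spec.grid.shape)

        stage = "preprocess"
        wm, csf = toy_tissue_masks(spec.grid)
        mean_fds, n_scrubbed = [], []
        if cfg.stages.preprocess:
            pp = cfg.preprocess
            processed = []
            for s in subjects:
                vol, scrub = run_preprocess(
                    s.volume, s.motion, wm, csf,
                    discard_n=pp.discard_n, fwhm_mm=pp.fwhm_mm,
                    low_hz=pp.low_hz, high_hz=pp.high_hz,
                    fd_threshold=pp.fd_threshold, n_back=pp.n_back,
                    n_forward=pp.n_forward, head_radius_mm=pp.head_radius_mm,
                )
                processed.append(vol)
                mean_fds.append(scrub.mean_fd)
                n_scrubbed.append(scrub.n_flagged)
            manifest["mean_fd"] = mean_fds
            manifest["timepoints_scrubbed"] = n_scrubbed
            demo = group_summary_table(manifest)
            demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        else:
            processed = [s.volume for s in subjects]

        stage = "pas"
        if not cfg.stages.pas:
            manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
            return out
        maps_dir = out / "pas_maps"
        maps_dir.mkdir(exist_ok=True)
        pas_maps = []
        for s, vol in zip(subjects, processed):
            pm = pas_map(
                vol, mask, r_threshold=cfg.pas.r_threshold,
                combine=cfg.pas.combine, chunk_size=cfg.pas.chunk_size,
            )
            pas_maps.append(pm)
            if pm.n_undefined:
                logger.warning(
                    "%s: %d voxels with undefined PAS", s.subject_id, pm.n_undefined
                )
            eligible_sel = pm.eligible[mask.in_mask]
            for name, vals in (("pas", pm.pas), ("fc_inter", pm.fc_inter),
                               ("fc_intra", pm.fc_intra)):
                full = np.zeros(mask.n_in_mask)
                full[eligible_sel] = np.nan_to_num(vals)
                save_map(full, mask, maps_dir / f"{s.subject_id}_{name}.nii")
            sidecar = {
                "r_threshold": pm.r_threshold, "combine": pm.combine,
                "n_undefined": pm.n_undefined,
                "n_eligible": int(pm.pas.size),
            }
            (maps_dir / f"{s.subject_id}.json").write_text(
                json.dumps(sidecar, indent=2) + "\n"
            )
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)

        stage = "group"
        if not cfg.stages.group:
            return out
        groups = manifest["group"].to_numpy()
        cov_cols = ["age"] + (["mean_fd"] if "mean_fd" in manifest else [])
        covariates = manifest[cov_cols]
        stat = two_sample_t_adjusted(pas_maps, groups, covariates)
        tgrid = stat.t_grid()
        save_map(np.nan_to_num(tgrid[mask.in_mask]), mask, out / "group_t.nii")
        for grp in ("patients", "controls"):
            osm = one_sample_t([m for m, g in zip(pas_maps, groups) if g == grp])
            save_map(
                np.nan_to_num(osm.t_grid()[mask.in_mask]), mask,
                out / f"one_sample_t_{grp}.nii",
            )
        if cfg.group.method == "grf":
            clusters = grf_cluster_correct(
                stat, voxel_p=cfg.group.voxel_p, cluster_p=cfg.group.cluster_p,
                connectivity=cfg.group.connectivity, two_sided=cfg.group.two_sided,
            )
        else:
            clusters = permutation_cluster_correct(
                pas_maps, groups, covariates,
                voxel_p=cfg.group.voxel_p, cluster_p=cfg.group.cluster_p,
                n_perm=cfg.group.n_perm, connectivity=cfg.group.connectivity,
                seed=cfg.seed,
            )
        clusters.to_tsv(out / "clusters.tsv")
        logger.info("group: %d surviving clusters", len(clusters))

        features = None
        if len(clusters) > 0:
            features = extract_cluster_means(pas_maps, clusters)
            features.insert(0, "subject_id", manifest["subject_id"].to_numpy())
            features.insert(1, "group", groups)
            features.to_csv(out / "cluster_means.tsv", sep="\t", index=False)

        stage = "correlate"
        if cfg.stages.correlate:
            if features is None:
                pd.DataFrame(
                    columns=["region", "score", "r", "p_uncorrected", "m_tests",
                             "bonferroni_alpha", "significant", "n"]
                ).to_csv(out / "correlations.tsv", sep="\t", index=False)
            else:
                pat = groups == "patients"
                feat_cols = [c for c in features.columns if c not in ("subject_id", "group")]
                results = pearson_with_bonferroni(
                    features.loc[pat, feat_cols].reset_index(drop=True),
                    manifest.loc[pat, cfg.correlate.scores].reset_index(drop=True),
                    alpha=cfg.correlate.alpha,
                )
                correlation_results_frame(results).to_csv(
                    out / "correlations.tsv", sep="\t", index=False
                )

        stage = "classify"
        if cfg.stages.classify:
            if features is None:
                pd.DataFrame(
                    columns=["region", "tp", "fn", "tn", "fp", "accuracy",
                             "sensitivity", "specificity", "n_total"]
                ).to_csv(out / "classification.tsv", sep="\t", index=False)
            else:
                feat_cols = [c for c in features.columns if c not in ("subject_id", "group")]
                if cfg.classify.grid == "coarse":
                    c_grid, g_grid = COARSE_C_GRID, COARSE_GAMMA_GRID
                else:
                    c_grid, g_grid = DEFAULT_C_GRID, DEFAULT_GAMMA_GRID
                table = classify_regions(
                    features[feat_cols], groups,
                    c_grid=c_grid, gamma_grid=g_grid,
                    inner_folds=cfg.classify.inner_folds, seed=cfg.seed,
                )
                table.to_csv(out / "classification.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return out
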