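"""End-to-end orchestration: subject-level extraction and group analysis.

``run_subject`` chains center-of-mass -> weighted-distance map -> top-K
selection -> delay embedding / divergence / lambda -> lambda map and
smoothing -> Morlet scalogram.  ``run_group`` applies it to a cohort and
runs the voxel-wise GLM, permutation FWE correction, and the
point-by-scale scalogram test, writing a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gmchaos import chaos, group_stats, scalogram, spatial_series, volume_io
from gmchaos.chaos import EmbeddingConfig, LambdaMap
from gmchaos.errors import GMChaosError
from gmchaos.scalogram import WaveletConfig
from gmchaos.volume_io import GMVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters for one reproducible run."""

    K: int = 5000
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    fwhm_mm: float = 8.0
    smooth: bool = True
    covariates: tuple[str, ...] = ()
    covariates_separately: bool = False
    n_perm: int = 1000
    q: float = 0.05
    cdt_p: float = 0.001
    extent: int = 10
    fdr_per_scale: bool = False
    run_fwe: bool = True
    seed: int = 0

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["embedding"] = dataclasses.asdict(self.embedding)
        d["wavelet"] = {
            "scales": self.wavelet.scales.tolist(),
            "omega0": self.wavelet.omega0,
            "output": self.wavelet.output,
        }
        d["covariates"] = list(self.covariates)
        return d


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except GMChaosError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        logger.info("stage=%s elapsed=%.3fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_subject(vol: GMVolume, cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full subject-level chain; returns all intermediate artifacts.

    Keys: com, wd_map, series, curve, lambda_estimate, lambda_series,
    lambda_map, smoothed_map, scalogram.
    """
    com = _stage("center_of_mass")(spatial_series.center_of_mass, vol)
    wd = _stage("weighted_distance_map")(spatial_series.weighted_distance_map, vol, com)
    series = _stage("sort_and_select")(spatial_series.sort_and_select, wd, cfg.K)
    traj = _stage("embed")(chaos.embed, series, cfg.embedding)
    nbrs = _stage("nearest_neighbors")(
        chaos.nearest_neighbors, traj, cfg.embedding.effective_theiler
    )
    curve = _stage("divergence_curve")(chaos.divergence_curve, traj, nbrs, cfg.embedding)
    estimate = _stage("lambda_global")(chaos.lambda_global, curve, cfg.embedding)
    lseries = _stage("lambda_local")(
        chaos.lambda_local, curve, cfg.embedding, series.voxel_indices, len(series)
    )
    lmap = _stage("lambda_map")(chaos.lambda_map, lseries, vol.data.shape, vol.affine)
    smoothed = (
        _stage("smooth_map")(chaos.smooth_map, lmap, cfg.fwhm_mm) if cfg.smooth else lmap
    )
    sgram = _stage("cwt")(scalogram.cwt, np.where(lseries.defined, lseries.values, 0.0),
                          cfg.wavelet)
    sgram.subject_id = vol.subject_id
    result = {
        "com": com,
        "wd_map": wd,
        "series": series,
        "curve": curve,
        "lambda_estimate": estimate,
        "lambda_series": lseries,
        "lambda_map": lmap,
        "smoothed_map": smoothed,
        "scalogram": sgram,
    }
    if out_dir is not None:
        _persist_subject(vol, result, cfg, Path(out_dir))
    return result


def _persist_subject(vol: GMVolume, result: dict, cfg: RunConfig, out_dir: Path) -> None:
    sub = out_dir / vol.subject_id
    sub.mkdir(parents=True, exist_ok=True)
    spatial_series.series_to_table(result["series"]).to_csv(
        sub / "series.tsv", sep="\t", index=False
    )
    curve = result["curve"]
    pd.DataFrame(
        {"step": curve.steps, "mean_log_div": curve.mean_log_div, "count": curve.counts}
    ).to_csv(sub / "divergence.tsv", sep="\t", index=False)
    volume_io.write_volume(
        GMVolume(result["lambda_map"].data, result["lambda_map"].affine, vol.subject_id),
        sub / "lambda_map.nii.gz",
    )
    volume_io.write_volume(
        GMVolume(result["smoothed_map"].data, result["smoothed_map"].affine, vol.subject_id),
        sub / "lambda_map_smoothed.nii.gz",
    )
    np.save(sub / "scalogram.npy", result["scalogram"].coeffs)


def run_group(
    volumes: list[GMVolume],
    table: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    atlas: np.ndarray | None = None,
) -> dict:
    """Subject chain for every volume, then group statistics.

    Subjects are matched to covariate rows by ``subject_id``; requested
    covariate columns are validated before any computation starts.
    Returns a dict with per-subject results, GLM/FWE results on the
    (smoothed) lambda maps, the scalogram group test, optional atlas
    region means, and the manifest.
    """
    table = volume_io._validate_covariates(table)
    for name in cfg.covariates:
        if name not in table.columns:
            raise GMChaosError(f"[stage validate] missing covariate column: {name}")
    by_id = {v.subject_id: v for v in volumes}
    missing = [s for s in table["subject_id"] if s not in by_id]
    if missing:
        raise GMChaosError(f"[stage validate] volumes missing for subjects: {missing}")
    shapes = {v.data.shape for v in volumes}
    if len(shapes) != 1:
        raise GMChaosError(f"[stage validate] inconsistent volume shapes: {shapes}")

    subject_results = {}
    for sid in table["subject_id"]:
        subject_results[sid] = run_subject(by_id[sid], cfg, out_dir=out_dir)

    maps = [subject_results[s]["smoothed_map"] for s in table["subject_id"]]
    covs = list(cfg.covariates)
    glm = group_stats.glm_contrast(maps, table, covs)
    fwe = None
    if cfg.run_fwe:
        fwe = group_stats.permutation_fwe(
            maps,
            table,
            covs,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            cdt_p=cfg.cdt_p,
            extent=cfg.extent,
        )
    groups = sorted(table["group"].astype(str).unique())
    sgrams = {
        g: [
            subject_results[s]["scalogram"]
            for s in table.loc[table["group"].astype(str) == g, "subject_id"]
        ]
        for g in groups
    }
    test_fn = (
        group_stats.scalogram_group_test_per_scale
        if cfg.fdr_per_scale
        else group_stats.scalogram_group_test
    )
    scale_test = test_fn(sgrams[groups[0]], sgrams[groups[1]], q=cfg.q)

    regions = None
    if atlas is not None:
        mean_map = LambdaMap(
            data=np.mean([m.data for m in maps], axis=0), affine=maps[0].affine
        )
        regions = group_stats.region_means(mean_map, atlas)

    manifest = {
        "config": cfg.to_manifest(),
        "n_subjects": len(volumes),
        "groups": {g: int((table["group"].astype(str) == g).sum()) for g in groups},
        "subjects": list(table["subject_id"]),
        "lambda_global": {
            s: subject_results[s]["lambda_estimate"].lambda_global
            for s in table["subject_id"]
        },
    }
    result = {
        "subjects": subject_results,
        "glm": glm,
        "fwe": fwe,
        "scale_test": scale_test,
        "regions": regions,
        "manifest": manifest,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = maps[0].affine
        volume_io.write_volume(GMVolume(glm.t_map, affine, "t"), out_dir / "t_map.nii.gz")
        volume_io.write_volume(GMVolume(glm.p_map, affine, "p"), out_dir / "p_map.nii.gz")
        if fwe is not None:
            volume_io.write_volume(
                GMVolume(fwe.corrected_p_map, affine, "pfwe"),
                out_dir / "corrected_p_map.nii.gz",
            )
            pd.DataFrame(
                [
                    {"size_voxels": c[0], "peak_i": c[1][0], "peak_j": c[1][1],
                     "peak_k": c[1][2], "peak_t": c[2]}
                    for c in fwe.clusters
                ]
            ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        sig = np.argwhere(scale_test.sig_mask)
        pd.DataFrame(
            {
                "point": sig[:, 0],
                "scale": cfg.wavelet.scales[sig[:, 1]].astype(float),
                "q_value": scale_test.q_grid[sig[:, 0], sig[:, 1]],
            }
        ).to_csv(out_dir / "significant_cells.tsv", sep="\t", index=False)
        if regions is not None:
            regions.to_csv(out_dir / "region_means.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
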