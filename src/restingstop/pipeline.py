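"""End-to-end pipeline: cohort -> preprocessing -> maps -> inference -> report.

Stage order follows the analysis chain: generate (or load) subject
volumes; smooth (6-mm FWHM); band-pass 0.01-0.08 Hz for ReHo and detrend
(no band-pass) for fALFF; standardize each map by its within-mask mean;
correlate voxelwise with SSRT, with and without age partialled out;
threshold at the critical r for alpha = 0.005 plus the Monte-Carlo
minimum cluster extent at corrected alpha = 0.05; and finally form the
max-r conjunction of the ReHo and fALFF maps (full pair and partial
pair), re-corrected with a freshly computed extent threshold.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import ConnectivityRule, MCThresholdResult, alphasim_kmin, apply_threshold
from .cohort import CohortConfig, SceneSpec, generate_subject_volume, null_scene, recovery_scene, sample_cohort
from .conjunction import conjunction_inference, conjunction_max_r
from .correlate import CorrelationMap, critical_r, voxelwise_correlation, voxelwise_partial_correlation
from .maps import BrainMap, SpectralBands, falff_map, reho_map, standardize_map
from .prep import BandSpec, VolumeSeries, bandpass, detrend, smooth_volume

__all__ = ["PipelineConfig", "PipelineResult", "subject_maps", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

SCENES = {"null": null_scene, "recovery": recovery_scene}


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    n_subjects: int = 40
    scene: str = "recovery"  # "null" | "recovery"
    grid: int = 24
    n_timepoints: int = 240
    include_age_region: bool = False
    age_ssrt_corr: float = 0.22
    fwhm_mm: float = 6.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    falff_den_high_hz: float = 0.25
    voxel_alpha: float = 0.005
    corrected_alpha: float = 0.05
    connectivity: int = 26
    mc_iterations: int = 1000
    standardize_maps: bool = True
    smooth_before_maps: bool = True
    seed: int = 0
    out_dir: str = "restingstop_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def build_scene(self) -> SceneSpec:
        if self.scene == "null":
            return null_scene(grid=self.grid, n_timepoints=self.n_timepoints)
        if self.scene == "recovery":
            return recovery_scene(
                grid=self.grid,
                n_timepoints=self.n_timepoints,
                include_age_region=self.include_age_region,
            )
        raise ValueError(f"unknown scene preset {self.scene!r}")


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline product."""

    cohort: pd.DataFrame
    scene: SceneSpec
    r_crit: float
    mc: MCThresholdResult
    mc_conjunction: MCThresholdResult
    corr_maps: dict[str, CorrelationMap]
    thresholded: dict[str, np.ndarray]
    tables: dict[str, pd.DataFrame]
    seeds: dict[str, int]
    config: PipelineConfig | None = None

    def survivor_mask(self, analysis: str) -> np.ndarray:
        """Boolean map of voxels surviving voxel+extent correction."""
        return np.isfinite(self.thresholded[analysis])


def subject_maps(
    series: VolumeSeries,
    fwhm_mm: float = 6.0,
    band: BandSpec = BandSpec(),
    bands: SpectralBands = SpectralBands(),
    standardize: bool = True,
    smooth_before_maps: bool = True,
) -> tuple[BrainMap, BrainMap]:
    """ReHo and fALFF maps for one subject.

    Default order mirrors the preprocessing chain: smooth, then band-pass
    into ReHo; the fALFF branch sees the smoothed, detrended but
    unfiltered series. ``smooth_before_maps=False`` computes both maps on
    unsmoothed data and smooths the maps afterwards instead (the
    alternative common in the ReHo literature, where pre-smoothing is
    avoided because it inflates neighborhood concordance).
    """
    from scipy import ndimage

    if smooth_before_maps:
        smoothed = smooth_volume(series, fwhm_mm)
        reho = reho_map(bandpass(smoothed, band))
        falff = falff_map(detrend(smoothed), bands)
    else:
        reho = reho_map(bandpass(series, band))
        falff = falff_map(detrend(series), bands)
        sigma = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / series.voxel_sizes_mm
        for m in (reho, falff):
            filled = np.where(np.isfinite(m.values), m.values, 0.0)
            m.values = np.where(m.mask, ndimage.gaussian_filter(filled, sigma, mode="constant"), np.nan)
    if standardize:
        reho = standardize_map(reho)
        falff = standardize_map(falff)
    return reho, falff


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - fail fast with the stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def analyze_cohort(
    cohort: pd.DataFrame,
    scene: SceneSpec,
    *,
    fwhm_mm: float = 6.0,
    band: BandSpec = BandSpec(),
    bands: SpectralBands = SpectralBands(),
    voxel_alpha: float = 0.005,
    corrected_alpha: float = 0.05,
    rule: ConnectivityRule = ConnectivityRule(),
    mc_iterations: int = 1000,
    standardize: bool = True,
    smooth_before_maps: bool = True,
    mc: MCThresholdResult | None = None,
    mc_conjunction: MCThresholdResult | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the analysis on an already-sampled cohort.

    Subject volumes are generated from each row's ``volume_seed`` and
    dropped once their maps are computed, so memory stays per-subject. A
    precomputed ``mc`` (and ``mc_conjunction``) may be supplied when
    several analyses share the same mask/FWHM/alpha configuration;
    otherwise both are computed here (the conjunction's extent threshold
    is recomputed with its own derived seed rather than reused).
    """
    compute_maps = _stage("maps")(_map_stacks)
    reho_stack, falff_stack = compute_maps(
        cohort, scene, fwhm_mm, band, bands, standardize, smooth_before_maps
    )
    ssrt = cohort["ssrt_ms"].to_numpy()
    age = cohort["age_years"].to_numpy()

    corr = _stage("correlate")(
        lambda: {
            "reho_full": voxelwise_correlation(reho_stack, ssrt, kind="reho_ssrt"),
            "falff_full": voxelwise_correlation(falff_stack, ssrt, kind="falff_ssrt"),
            "reho_partial": voxelwise_partial_correlation(reho_stack, ssrt, age, kind="reho_ssrt"),
            "falff_partial": voxelwise_partial_correlation(falff_stack, ssrt, age, kind="falff_ssrt"),
        }
    )()
    corr["conjunction_full"] = conjunction_max_r(corr["reho_full"], corr["falff_full"])
    corr["conjunction_partial"] = conjunction_max_r(corr["reho_partial"], corr["falff_partial"])

    r_crit_full = critical_r(voxel_alpha, corr["reho_full"].df, tails=2)
    mc_seed = seed + 1_000_003
    if mc is None:
        mc = _stage("alphasim")(alphasim_kmin)(
            scene.mask,
            fwhm_mm,
            voxel_alpha,
            corrected_alpha,
            voxel_mm=scene.voxel_mm,
            rule=rule,
            n_iterations=mc_iterations,
            seed=mc_seed,
        )
    if mc_conjunction is None:
        mc_conjunction = _stage("alphasim-conj")(alphasim_kmin)(
            scene.mask,
            fwhm_mm,
            voxel_alpha,
            corrected_alpha,
            voxel_mm=scene.voxel_mm,
            rule=rule,
            n_iterations=mc_iterations,
            seed=mc_seed + 1,
        )

    thresholded: dict[str, np.ndarray] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name in ("reho_full", "falff_full", "reho_partial", "falff_partial"):
        rc = critical_r(voxel_alpha, corr[name].df, tails=2)
        thresholded[name], tables[name] = apply_threshold(
            corr[name], rc, mc.k_min, sign="negative", rule=rule
        )
    for name in ("conjunction_full", "conjunction_partial"):
        rc = critical_r(voxel_alpha, corr[name].df, tails=2)
        thresholded[name], tables[name] = conjunction_inference(
            corr[name], rc, mc_conjunction, rule=rule
        )

    return PipelineResult(
        cohort=cohort,
        scene=scene,
        r_crit=r_crit_full,
        mc=mc,
        mc_conjunction=mc_conjunction,
        corr_maps=corr,
        thresholded=thresholded,
        tables=tables,
        seeds={"analysis": seed, "alphasim": mc.seed, "alphasim_conjunction": mc_conjunction.seed},
    )


def _map_stacks(cohort, scene, fwhm_mm, band, bands, standardize, smooth_before_maps):
    reho_stack: list[BrainMap] = []
    falff_stack: list[BrainMap] = []
    for _, row in cohort.iterrows():
        series = generate_subject_volume(row, scene, int(row["volume_seed"]))
        reho, falff = subject_maps(
            series, fwhm_mm, band, bands, standardize, smooth_before_maps
        )
        reho_stack.append(reho)
        falff_stack.append(falff)
    return reho_stack, falff_stack


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full run from config: sample cohort, analyze, write the report bundle.

    Writes per-analysis cluster tables (four parent analyses plus the two
    conjunctions), all correlation and thresholded maps as NIfTI, the
    cohort TSV, and a JSON run log carrying every seed and threshold.
    """
    t0 = time.perf_counter()
    scene = _stage("scene")(config.build_scene)()
    cohort_cfg = CohortConfig(age_ssrt_corr=config.age_ssrt_corr)
    cohort = _stage("cohort")(sample_cohort)(config.n_subjects, cohort_cfg, config.seed)
    result = analyze_cohort(
        cohort,
        scene,
        fwhm_mm=config.fwhm_mm,
        band=BandSpec(config.band_low_hz, config.band_high_hz),
        bands=SpectralBands(
            config.band_low_hz, config.band_high_hz, config.band_low_hz, config.falff_den_high_hz
        ),
        voxel_alpha=config.voxel_alpha,
        corrected_alpha=config.corrected_alpha,
        rule=ConnectivityRule(config.connectivity),
        mc_iterations=config.mc_iterations,
        standardize=config.standardize_maps,
        smooth_before_maps=config.smooth_before_maps,
        seed=config.seed,
    )
    result.config = config

    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    for name, table in result.tables.items():
        table.to_csv(out / "tables" / f"clusters_{name}.tsv", sep="\t", index=False)
    aff = scene.affine
    for name, cmap in result.corr_maps.items():
        nib.save(nib.Nifti1Image(cmap.r_values.astype(np.float32), aff), out / "maps" / f"r_{name}.nii.gz")
    for name, vals in result.thresholded.items():
        nib.save(
            nib.Nifti1Image(vals.astype(np.float32), aff),
            out / "maps" / f"thresholded_{name}.nii.gz",
        )
    nib.save(nib.Nifti1Image(scene.mask.astype(np.uint8), aff), out / "maps" / "mask.nii.gz")
    nib.save(nib.Nifti1Image(scene.truth_labels(), aff), out / "maps" / "truth_labels.nii.gz")

    log = {
        "version": __version__,
        "config": asdict(config),
        "seeds": result.seeds,
        "n_subjects": int(len(cohort)),
        "df_full": result.corr_maps["reho_full"].df,
        "df_partial": result.corr_maps["reho_partial"].df,
        "r_crit_full": result.r_crit,
        "k_min": result.mc.k_min,
        "k_min_conjunction": result.mc_conjunction.k_min,
        "connectivity": config.connectivity,
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    logger.info("pipeline finished in %.1fs -> %s", time.perf_counter() - t0, out)
    return result
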