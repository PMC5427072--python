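"""Synthetic cohort generator with known brain-behavior ground truth.

Builds a cohort of middle-aged/elderly subjects (ages 40-77): each
subject gets race-model parameters, a simulated stop-signal session (so
the SSRT is *estimated* from behavior, as in a real study), and a 4D
BOLD-like volume whose local synchrony and low-frequency amplitude encode
configurable couplings to the subject's latent stop latency or age.

Effect models
-------------
synchrony   Every voxel in the region shares a fraction rho of its
            variance with a region-common WHITE signal:
            voxel = sqrt(rho)*common + sqrt(1-rho)*private. A white
            common signal raises Kendall's W of the band-passed series
            (the ReHo readout) while leaving the spectrum — and hence
            fALFF — flat: the two readouts stay orthogonal by design.
amplitude   Each voxel independently receives a band-limited
            (0.01-0.08 Hz) component with subject gain a, raising fALFF
            without creating any cross-voxel synchrony.
both        Both effects at once.
age_only    Both effects, driven by the subject's age instead of SSRT.

Couplings are affine in the standardized driver (clipped to +/-2.5 sd)
with negative sign by default: slower stopping (higher SSRT) means lower
local synchrony and lower low-frequency amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .prep import VolumeSeries
from .task import RaceModelParams, build_trial_sequence, estimate_ssrt, simulate_subject

__all__ = [
    "EffectRegion",
    "SceneSpec",
    "CohortConfig",
    "sample_cohort",
    "generate_subject_volume",
    "write_cohort",
    "ball_mask",
    "cube_region",
    "null_scene",
    "recovery_scene",
]

EFFECT_KINDS = ("synchrony", "amplitude", "both", "age_only")
Z_CLIP = 2.5


@dataclass
class EffectRegion:
    """A labeled voxel set with its coupling model."""

    name: str
    indicator: np.ndarray  # 3-D bool
    kind: str
    sign: float = -1.0  # negative coupling: higher driver -> weaker effect
    rho_mean: float = 0.45
    rho_slope: float = 0.22
    rho_max: float = 0.9
    gain_mean: float = 1.0
    gain_slope: float = 0.4
    gain_max: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"kind must be one of {EFFECT_KINDS}")
        self.indicator = np.asarray(self.indicator, dtype=bool)

    @property
    def driver(self) -> str:
        return "age" if self.kind == "age_only" else "ssrt"

    @property
    def has_synchrony(self) -> bool:
        return self.kind in ("synchrony", "both", "age_only")

    @property
    def has_amplitude(self) -> bool:
        return self.kind in ("amplitude", "both", "age_only")

    def rho(self, z: float) -> float:
        z = float(np.clip(z, -Z_CLIP, Z_CLIP))
        return float(np.clip(self.rho_mean + self.sign * self.rho_slope * z, 0.0, self.rho_max))

    def gain(self, z: float) -> float:
        z = float(np.clip(z, -Z_CLIP, Z_CLIP))
        return float(np.clip(self.gain_mean + self.sign * self.gain_slope * z, 0.0, self.gain_max))


@dataclass
class SceneSpec:
    """Grid geometry, acquisition timing, mask and effect layout."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_mm: float = 2.0
    tr_s: float = 2.0
    n_timepoints: int = 240
    mask: np.ndarray | None = None
    effect_regions: list[EffectRegion] = field(default_factory=list)
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08

    def __post_init__(self) -> None:
        if self.n_timepoints < 64:
            raise ValueError("n_timepoints must be >= 64")
        if self.mask is None:
            self.mask = ball_mask(self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape must equal grid_shape")
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for region in self.effect_regions:
            if region.indicator.shape != tuple(self.grid_shape):
                raise ValueError(f"region {region.name}: indicator shape mismatch")
            if np.any(region.indicator & ~self.mask):
                raise ValueError(f"region {region.name}: voxels outside the mask")
            if np.any(region.indicator & occupied):
                raise ValueError(f"region {region.name}: overlaps another region")
            occupied |= region.indicator

    @property
    def affine(self) -> np.ndarray:
        """Toy MNI-like affine: isotropic voxels, origin at the grid center."""
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_mm
        return aff

    def truth_labels(self) -> np.ndarray:
        labels = np.zeros(self.grid_shape, dtype=np.int16)
        for i, region in enumerate(self.effect_regions, start=1):
            labels[region.indicator] = i
        return labels


def ball_mask(shape: tuple[int, int, int], radius_vox: float | None = None) -> np.ndarray:
    """Centered spherical in-brain mask (default radius: 45% of min extent)."""
    shape = tuple(shape)
    if radius_vox is None:
        radius_vox = 0.45 * min(shape)
    center = (np.array(shape) - 1) / 2.0
    grid = np.indices(shape).reshape(3, -1).T
    dist = np.sqrt(((grid - center) ** 2).sum(axis=1)).reshape(shape)
    return dist <= radius_vox


def cube_region(shape: tuple[int, int, int], corner: tuple[int, int, int], size: int) -> np.ndarray:
    ind = np.zeros(shape, dtype=bool)
    sl = tuple(slice(c, c + size) for c in corner)
    ind[sl] = True
    return ind


def null_scene(
    grid: int = 24, n_timepoints: int = 240, voxel_mm: float = 2.0, tr_s: float = 2.0
) -> SceneSpec:
    """Scene with no injected effects (pure noise cohort)."""
    shape = (grid, grid, grid)
    return SceneSpec(
        grid_shape=shape,
        voxel_mm=voxel_mm,
        tr_s=tr_s,
        n_timepoints=n_timepoints,
        mask=ball_mask(shape, radius_vox=0.46 * grid),
    )


def recovery_scene(
    grid: int = 24,
    n_timepoints: int = 240,
    include_age_region: bool = False,
    cube: int = 5,
) -> SceneSpec:
    """Four well-separated cubic regions inside a spherical mask.

    Layout (24-grid reference): a synchrony-only, an amplitude-only and a
    "both" cube, plus optionally an age-driven cube with stronger
    couplings. The cubes are >= 12 mm apart so 6-mm smoothing cannot
    bridge them.
    """
    shape = (grid, grid, grid)
    mask = ball_mask(shape, radius_vox=0.46 * grid)
    lo = round(grid / 6)
    hi = grid - lo - cube
    mid = (grid - cube) // 2
    regions = [
        EffectRegion("synchrony_only", cube_region(shape, (lo, lo, mid), cube), "synchrony"),
        EffectRegion("amplitude_only", cube_region(shape, (hi, lo, mid), cube), "amplitude"),
        EffectRegion("both_effects", cube_region(shape, (lo, hi, mid), cube), "both"),
    ]
    if include_age_region:
        regions.append(
            EffectRegion(
                "age_only",
                cube_region(shape, (hi, hi, mid), cube),
                "age_only",
                rho_mean=0.6,
                rho_slope=0.35,
                gain_mean=1.4,
                gain_slope=0.7,
            )
        )
    return SceneSpec(grid_shape=shape, n_timepoints=n_timepoints, mask=mask, effect_regions=regions)


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of the synthetic cohort.

    Ages are uniform on ``age_range``; the latent stop latency is Gaussian
    with the configured population correlation to age. Behavioral defaults
    mirror a five-block session of 140 trials (40 stop) per block.
    """

    age_range: tuple[float, float] = (40.0, 77.0)
    age_ssrt_corr: float = 0.22
    ssrt_mean_ms: float = 300.0
    ssrt_sd_ms: float = 50.0
    go_mu_mean_ms: float = 500.0
    go_mu_sd_ms: float = 40.0
    go_sigma_ms: float = 50.0
    go_tau_ms: float = 175.0
    omission_rate: float = 0.1124
    choice_error_rate: float = 0.0207
    blocks: int = 5
    trials_per_block: int = 140
    stop_per_block: int = 40

    def __post_init__(self) -> None:
        if not (-1 < self.age_ssrt_corr < 1):
            raise ValueError("age_ssrt_corr must lie in (-1, 1)")


def sample_cohort(
    n_subjects: int, config: CohortConfig = CohortConfig(), seed: int = 0
) -> pd.DataFrame:
    """Sample ages and race parameters, then simulate each subject's session.

    Returns one row per subject with latent parameters (true_ssrt_ms, the
    standardized drivers ssrt_z / age_z, a per-subject volume seed) and
    the behavioral summary estimated from the simulated session
    (ssrt_ms, median go RT, median SSD, stop-success %).
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3 (correlation undefined below)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, n_subjects)
    # population standardization of a uniform age: mean (lo+hi)/2, sd (hi-lo)/sqrt(12)
    age_z_pop = (ages - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    r = config.age_ssrt_corr
    eps = rng.standard_normal(n_subjects)
    true_ssrt = config.ssrt_mean_ms + config.ssrt_sd_ms * (
        r * age_z_pop + np.sqrt(1 - r**2) * eps
    )
    true_ssrt = np.clip(true_ssrt, 80.0, None)  # keep the stop process physical
    mus = rng.normal(config.go_mu_mean_ms, config.go_mu_sd_ms, n_subjects)

    task_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_subjects)]
    vol_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_subjects)]
    rows = []
    for i in range(n_subjects):
        params = RaceModelParams(
            mu_ms=float(mus[i]),
            sigma_ms=config.go_sigma_ms,
            tau_ms=config.go_tau_ms,
            true_ssrt_ms=float(true_ssrt[i]),
            omission_rate=config.omission_rate,
            choice_error_rate=config.choice_error_rate,
        )
        plan = build_trial_sequence(
            config.blocks, config.trials_per_block, config.stop_per_block, task_seeds[i]
        )
        summary = estimate_ssrt(simulate_subject(params, plan, task_seeds[i] + 1))
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "age_years": float(ages[i]),
                "mu_ms": params.mu_ms,
                "sigma_ms": params.sigma_ms,
                "tau_ms": params.tau_ms,
                "true_ssrt_ms": params.true_ssrt_ms,
                "omission_rate": params.omission_rate,
                "choice_error_rate": params.choice_error_rate,
                "median_go_rt_ms": summary.median_go_rt_ms,
                "median_ssd_ms": summary.median_ssd_ms,
                "stop_success_pct": summary.stop_success_rate,
                "go_accuracy_pct": summary.go_accuracy_pct,
                "omission_pct": summary.omission_pct,
                "ssrt_ms": summary.ssrt_ms,
                "ssrt_z": (params.true_ssrt_ms - config.ssrt_mean_ms) / config.ssrt_sd_ms,
                "age_z": float(age_z_pop[i]),
                "volume_seed": vol_seeds[i],
            }
        )
    return pd.DataFrame(rows)


def _bandlimited_noise(
    rng: np.random.Generator, n_series: int, n_t: int, tr_s: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Unit-variance rows of band-limited (hard passband) white noise."""
    w = rng.standard_normal((n_series, n_t), dtype=np.float32)
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = (freqs >= low_hz) & (freqs < high_hz) & (freqs > 0)
    spec = np.fft.rfft(w, axis=-1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_t, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_subject_volume(subject_row, scene: SceneSpec, seed: int) -> VolumeSeries:
    """One subject's 4D volume: unit-variance noise plus region effects.

    Background voxels are independent white noise; each effect region
    applies its synchrony and/or amplitude model at the level set by the
    subject's standardized driver (ssrt_z or age_z). Masked-out voxels
    are exactly zero. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(scene.grid_shape)
    n_t = scene.n_timepoints
    data = rng.standard_normal(shape + (n_t,), dtype=np.float32)
    for region in scene.effect_regions:
        z = float(subject_row["age_z" if region.driver == "age" else "ssrt_z"])
        idx = region.indicator
        nvox = int(idx.sum())
        rho = region.rho(z) if region.has_synchrony else 0.0
        a = region.gain(z) if region.has_amplitude else 0.0
        # common and private components share one spectral template,
        # (white + a*low)/sqrt(1+a^2): the shared variance fraction is then
        # exactly rho whatever a is, and the per-voxel spectrum (the fALFF
        # readout) depends only on a whatever rho is — even after spatial
        # smoothing, which preserves the coherent (common) part unattenuated
        norm = np.float32(1.0 / np.sqrt(1.0 + a**2))
        common = rng.standard_normal(n_t, dtype=np.float32)
        common_low = _bandlimited_noise(
            rng, 1, n_t, scene.tr_s, scene.band_low_hz, scene.band_high_hz
        )[0]
        private_low = _bandlimited_noise(
            rng, nvox, n_t, scene.tr_s, scene.band_low_hz, scene.band_high_hz
        )
        common = (common + np.float32(a) * common_low) * norm
        private = (data[idx] + np.float32(a) * private_low) * norm
        data[idx] = np.float32(np.sqrt(rho)) * common + np.float32(np.sqrt(1 - rho)) * private
    data[~scene.mask] = 0.0
    return VolumeSeries(data=data, mask=scene.mask, affine=scene.affine, tr_s=scene.tr_s)


def write_cohort(
    cohort: pd.DataFrame,
    volumes: dict[str, VolumeSeries],
    out_dir: str | Path,
    scene: SceneSpec,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write one 4D NIfTI per subject plus cohort TSV, mask and truth labels."""
    out_dir = Path(out_dir)
    missing = set(cohort["subject_id"]) - set(volumes)
    if missing:
        raise ValueError(f"volumes missing for subjects: {sorted(missing)}")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _target(name: str) -> Path:
        p = out_dir / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    aff = scene.affine
    for sid in cohort["subject_id"]:
        series = volumes[sid]
        img = nib.Nifti1Image(series.data.astype(np.float32), aff)
        img.header.set_zooms((scene.voxel_mm,) * 3 + (scene.tr_s,))
        img.header.set_xyzt_units("mm", "sec")
        p = _target(f"{sid}_bold.nii.gz")
        nib.save(img, p)
        paths[sid] = p

    p = _target("cohort.tsv")
    cohort.to_csv(p, sep="\t", index=False)
    paths["cohort"] = p

    mask_img = nib.Nifti1Image(scene.mask.astype(np.uint8), aff)
    p = _target("mask.nii.gz")
    nib.save(mask_img, p)
    paths["mask"] = p

    labels_img = nib.Nifti1Image(scene.truth_labels(), aff)
    p = _target("truth_labels.nii.gz")
    nib.save(labels_img, p)
    paths["truth_labels"] = p

    regions = pd.DataFrame(
        {
            "label": np.arange(1, len(scene.effect_regions) + 1),
            "name": [r.name for r in scene.effect_regions],
            "kind": [r.kind for r in scene.effect_regions],
            "size_voxels": [int(r.indicator.sum()) for r in scene.effect_regions],
        }
    )
    p = _target("regions.tsv")
    regions.to_csv(p, sep="\t", index=False)
    paths["regions"] = p
    return paths
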