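"""Simulated geographic-atrophy trial cohort with known ground truth.

Each simulated eye carries a multifocal atrophic lesion whose square-root
area grows linearly in time — the growth law that makes √area the natural
trial endpoint — rendered by thresholding the Euclidean distance transform
of a set of seed points, so separate foci merge naturally as they expand
(focality can decrease while area grows, as in real GA).  Photoreceptor
degeneration spatially leads RPE loss (a halo annulus), hypertransmission
is co-located with RPE loss up to boundary noise, and the recorded fovea
position carries localisation jitter.  Treatment arms scale the growth
rate by a multiplier.

Two granularities are offered: :func:`simulate_cohort` renders full
segmentation volumes (B-scan stacks) for pipeline-level validation, and
:func:`simulate_growth_table` draws measured lesion trajectories directly
on the area scale for statistical calibration at scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .feature_derivation import ALL_FEATURES
from .io_formats import ARMS, SegmentationVolume, VolumeMeta, write_volume

# default arm multipliers on the sham sqrt-area growth rate; the sham rate
# 0.277 mm/yr and the ratios 0.151/0.277, 0.202/0.277 mirror the FILLY
# 12-month qOCT means for monthly/every-other-month pegcetacoplan vs sham
DEFAULT_SHAM_GROWTH = 0.277
DEFAULT_ARM_EFFECT = {"SHAM": 1.0, "PEOM": 0.202 / 0.277, "PM": 0.151 / 0.277}


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) clipped to [lo, hi] by resampling."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise RuntimeError("truncated-normal rejection sampling failed")


@dataclass(frozen=True)
class TruncatedGeometric:
    """Geometric distribution on {1..max_k} with a prescribed truncated mean.

    The success probability is solved by bisection so that the truncated
    mean hits ``mean`` (default 3.14 lesions, max 12 — the observed
    focality distribution of the study population).
    """

    mean: float = 3.14
    max_k: int = 12

    def _pmf(self, p: float) -> np.ndarray:
        k = np.arange(1, self.max_k + 1)
        w = (1 - p) ** (k - 1) * p
        return w / w.sum()

    def probabilities(self) -> np.ndarray:
        lo, hi = 1e-6, 1 - 1e-6
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            m = float((self._pmf(mid) * np.arange(1, self.max_k + 1)).sum())
            if m > self.mean:
                lo = mid
            else:
                hi = mid
        return self._pmf(0.5 * (lo + hi))

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(np.arange(1, self.max_k + 1), p=self.probabilities()))


@dataclass(frozen=True)
class CohortConfig:
    """Simulator parameterisation; defaults reflect the study conditions."""

    n_per_arm: dict = field(
        default_factory=lambda: {"PM": 10, "PEOM": 10, "SHAM": 10}
    )
    visit_months: tuple[int, ...] = (0, 2, 6, 12, 18)
    grid_px: tuple[int, int] = (600, 600)
    field_extent_mm: tuple[float, float] = (6.0, 6.0)
    n_bscans: int = 49
    axial_px: int = 8
    sham_sqrt_growth_mm_per_year: float = DEFAULT_SHAM_GROWTH
    arm_effect: dict = field(default_factory=lambda: dict(DEFAULT_ARM_EFFECT))
    focality_dist: TruncatedGeometric = TruncatedGeometric()
    baseline_sqrt_area_dist: TruncatedNormal = TruncatedNormal(2.6, 0.6, 1.26, 4.07)
    prd_halo_mm: float = 0.25
    htr_agreement: float = 0.95
    fovea_jitter_mm: float = 0.05
    growth_cv: float = 0.4
    sqrt_noise_sd_mm: float = 0.10
    min_seed_sep_mm: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(a not in ARMS for a in self.n_per_arm):
            raise ValueError(f"arms must be among {ARMS}")
        if self.arm_effect.get("SHAM") != 1.0:
            raise ValueError("arm_effect['SHAM'] must be 1")
        vm = list(self.visit_months)
        if vm != sorted(vm) or vm[0] != 0:
            raise ValueError("visit_months must be ascending and start at 0")
        if not 0.0 <= self.htr_agreement <= 1.0:
            raise ValueError("htr_agreement must be in [0, 1]")
        for name in ("prd_halo_mm", "fovea_jitter_mm", "growth_cv", "sqrt_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def px_mm(self) -> float:
        return self.field_extent_mm[0] / self.grid_px[1]


@dataclass
class GroundTruth:
    """Per eye-visit true areas, focality and fovea of the simulated cohort."""

    table: pd.DataFrame

    def eye(self, eye_id: str) -> pd.DataFrame:
        return self.table[self.table.eye_id == eye_id]


def _eye_rng(root_seed: int, arm_index: int, eye_index: int) -> np.random.Generator:
    # counter-based splitting: reproducible regardless of iteration order
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(arm_index, eye_index))
    return np.random.default_rng(ss)


def _place_seeds(
    rng: np.random.Generator, k: int, cfg: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Seed points and radial offsets for a multifocal lesion.

    Returns k points (mm, (y, x)) at least ``min_seed_sep_mm`` apart within
    the central macula, and per-seed radial offsets: the first (dominant)
    focus has offset 0, satellites carry a positive offset so they render
    smaller than the main lesion — the typical configuration of multifocal
    GA, where a large lesion is accompanied by smaller foci.
    """
    ext = cfg.field_extent_mm
    margin = 1.2
    pts: list[np.ndarray] = []
    for _ in range(10000):
        cand = np.array(
            [
                rng.uniform(margin, ext[1] - margin),
                rng.uniform(margin, ext[0] - margin),
            ]
        )
        if all(np.linalg.norm(cand - p) >= cfg.min_seed_sep_mm for p in pts):
            pts.append(cand)
            if len(pts) == k:
                break
    else:
        raise RuntimeError("could not place lesion seeds with the requested separation")
    offsets = np.concatenate([[0.0], rng.uniform(0.3, 0.9, k - 1)])
    return np.array(pts), offsets


def _mask_for_sqrt_area(
    dsort: np.ndarray, dist: np.ndarray, sqrt_area_mm: float, px_mm: float
) -> np.ndarray:
    """Threshold the distance field so the mask area hits sqrt_area_mm²."""
    n_px = int(round(sqrt_area_mm**2 / px_mm**2))
    n_px = max(n_px, 1)
    if n_px > dsort.size:
        raise ValueError(
            f"target area {sqrt_area_mm**2:.1f} mm² exceeds the simulated field"
        )
    return dist <= dsort[n_px - 1]


@dataclass
class _EyeRender:
    eye_id: str
    arm: str
    truth_rows: list
    enface_truth: dict  # visit -> {feature: raster}
    recorded_fovea_mm: dict  # visit -> (x, y)
    growth_rate: float


def _simulate_eye(
    cfg: CohortConfig, arm: str, arm_index: int, eye_index: int
) -> _EyeRender:
    rng = _eye_rng(cfg.rng_seed, arm_index, eye_index)
    eye_id = f"{arm}-{eye_index:03d}"
    laterality = "OD" if rng.random() < 0.5 else "OS"

    k = cfg.focality_dist.sample(rng)
    seeds_mm, seed_offsets = _place_seeds(rng, k, cfg)
    s0 = cfg.baseline_sqrt_area_dist.sample(rng)
    mult = 1.0
    if cfg.growth_cv > 0:
        sigma2 = np.log1p(cfg.growth_cv**2)
        mult = float(rng.lognormal(-sigma2 / 2, np.sqrt(sigma2)))
    rate = cfg.arm_effect[arm] * cfg.sham_sqrt_growth_mm_per_year * mult

    px = cfg.px_mm
    nrow, ncol = cfg.grid_px
    # offset distance field: dist(x) = min_j (|x - seed_j| + offset_j), so
    # thresholding at r yields the dominant focus with radius r plus
    # satellites of radius r - offset_j; foci merge naturally as r grows
    ys = (np.arange(nrow) + 0.5) * px
    xs = (np.arange(ncol) + 0.5) * px
    dist = np.full((nrow, ncol), np.inf)
    for (sy, sx), off in zip(seeds_mm, seed_offsets):
        np.minimum(dist, np.hypot(ys[:, None] - sy, xs[None, :] - sx) + off, out=dist)
    dsort = np.sort(dist.ravel())

    true_fovea_mm = (cfg.field_extent_mm[0] / 2, cfg.field_extent_mm[1] / 2)
    fc = (true_fovea_mm[0] / px, true_fovea_mm[1] / px)
    yy, xx = np.ogrid[0:nrow, 0:ncol]
    disc = (yy - fc[1]) ** 2 + (xx - fc[0]) ** 2 < (3.0 / px) ** 2

    final_sqrt = s0 + rate * cfg.visit_months[-1] / 12
    if final_sqrt**2 > 0.9 * cfg.field_extent_mm[0] * cfg.field_extent_mm[1]:
        raise ValueError(
            f"eye {eye_id}: lesion would outgrow the field "
            f"(final area {final_sqrt**2:.1f} mm²)"
        )

    truth_rows = []
    enface_truth: dict[int, dict[str, np.ndarray]] = {}
    recorded: dict[int, tuple[float, float]] = {}
    px2 = px * px
    for month in cfg.visit_months:
        target = s0 + rate * month / 12
        rpe = _mask_for_sqrt_area(dsort, dist, target, px)
        prd = (
            dist <= dsort[int(rpe.sum()) - 1] + cfg.prd_halo_mm
            if cfg.prd_halo_mm > 0
            else rpe.copy()
        )
        htr = rpe.copy()
        if cfg.htr_agreement < 1.0:
            boundary = rpe & ~ndimage.binary_erosion(rpe)
            drop = boundary & (rng.random(rpe.shape) > cfg.htr_agreement)
            htr &= ~drop
        rora = rpe & prd & htr
        prd_iso = prd & ~rpe & ~htr
        intact = disc & ~(rpe | prd | htr)
        focality = ndimage.label(rpe, structure=np.ones((3, 3)))[1]

        jitter = rng.normal(0.0, cfg.fovea_jitter_mm, size=2)
        recorded[month] = (true_fovea_mm[0] + jitter[0], true_fovea_mm[1] + jitter[1])

        areas = {
            "RPE_LOSS": rpe.sum() * px2,
            "PRD": prd.sum() * px2,
            "HTR": htr.sum() * px2,
            "RORA": rora.sum() * px2,
            "PRD_ISOLATED": prd_iso.sum() * px2,
            "INTACT_MACULA": intact.sum() * px2,
        }
        truth_rows.append(
            {
                "eye_id": eye_id,
                "arm": arm,
                "visit_month": month,
                **{f"area_{k_}": float(v) for k_, v in areas.items()},
                "focality": int(focality),
                "target_sqrt_area_mm": float(target),
                "growth_rate_mm_per_year": float(rate),
                "fovea_true_x_mm": true_fovea_mm[0],
                "fovea_true_y_mm": true_fovea_mm[1],
                "fovea_recorded_x_mm": recorded[month][0],
                "fovea_recorded_y_mm": recorded[month][1],
                "laterality": laterality,
            }
        )
        enface_truth[month] = {
            "RPE_LOSS": rpe,
            "PRD": prd,
            "HTR": htr,
            "RORA": rora,
            "PRD_ISOLATED": prd_iso,
            "INTACT_MACULA": intact,
        }
    return _EyeRender(eye_id, arm, truth_rows, enface_truth, recorded, rate)


def _slice_to_volume(
    truth_raster: np.ndarray, cfg: CohortConfig, meta: VolumeMeta, feature: str
) -> SegmentationVolume:
    """Cut an en-face truth raster into equal-height B-scan bands.

    An A-scan is positive iff any truth pixel of its band is positive,
    matching the downstream per-A-scan reduction; positive A-scans are
    rendered as a fixed axial band inside each B-scan.
    """
    nrow, ncol = truth_raster.shape
    edges = np.linspace(0, nrow, cfg.n_bscans + 1).round().astype(int)
    masks = np.zeros((cfg.n_bscans, cfg.axial_px, ncol), bool)
    a0, a1 = 2, max(3, cfg.axial_px - 2)
    for i in range(cfg.n_bscans):
        band = truth_raster[edges[i] : edges[i + 1]]
        if band.size:
            cols = band.any(axis=0)
            masks[i, a0:a1, cols] = True
    return SegmentationVolume(meta=meta, feature=feature, masks=masks)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[list[SegmentationVolume]], GroundTruth]:
    """Render the cohort as segmentation-volume groups plus ground truth.

    Returns one group (the three constituent-feature volumes) per eye-visit
    and a :class:`GroundTruth` table with true areas, focality, fovea and
    growth rate for every eye-visit.
    """
    groups: list[list[SegmentationVolume]] = []
    rows: list[dict] = []
    bspacing = config.field_extent_mm[1] / config.n_bscans
    aspacing = config.field_extent_mm[0] / config.grid_px[1]
    for arm_index, arm in enumerate(a for a in ARMS if a in config.n_per_arm):
        for eye_index in range(config.n_per_arm[arm]):
            eye = _simulate_eye(config, arm, arm_index, eye_index)
            rows.extend(eye.truth_rows)
            laterality = eye.truth_rows[0]["laterality"]
            for month in config.visit_months:
                meta = VolumeMeta(
                    eye_id=eye.eye_id,
                    arm=arm,
                    visit_month=month,
                    laterality=laterality,
                    n_bscans=config.n_bscans,
                    ascan_spacing_mm=aspacing,
                    bscan_spacing_mm=bspacing,
                    fovea_xy_mm=eye.recorded_fovea_mm[month],
                    field_extent_mm=config.field_extent_mm,
                    acquisition_id=f"{eye.eye_id}-m{month:02d}",
                )
                group = [
                    _slice_to_volume(eye.enface_truth[month][f], config, meta, f)
                    for f in ("RPE_LOSS", "PRD", "HTR")
                ]
                groups.append(group)
    truth = GroundTruth(pd.DataFrame(rows, columns=_truth_columns()))
    return groups, truth


def _truth_columns() -> list[str]:
    return (
        ["eye_id", "arm", "visit_month"]
        + [f"area_{f}" for f in ALL_FEATURES]
        + [
            "focality",
            "target_sqrt_area_mm",
            "growth_rate_mm_per_year",
            "fovea_true_x_mm",
            "fovea_true_y_mm",
            "fovea_recorded_x_mm",
            "fovea_recorded_y_mm",
            "laterality",
        ]
    )


def simulate_growth_table(config: CohortConfig) -> pd.DataFrame:
    """Measured RORA area trajectories without rasterisation.

    Draws, per eye, a baseline √area and a growth rate (arm multiplier ×
    sham rate × lognormal between-eye factor), then adds per-visit
    measurement noise on the √area scale.  Returns a long table with
    columns eye_id, arm, visit_month, feature, area_mm2 ready for
    :func:`qoctga.trial_endpoints.build_long_table`.  Used for statistical
    calibration where rendering every eye would be waste.
    """
    rows = []
    for arm_index, arm in enumerate(a for a in ARMS if a in config.n_per_arm):
        for eye_index in range(config.n_per_arm[arm]):
            rng = _eye_rng(config.rng_seed, arm_index, eye_index)
            s0 = config.baseline_sqrt_area_dist.sample(rng)
            mult = 1.0
            if config.growth_cv > 0:
                sigma2 = np.log1p(config.growth_cv**2)
                mult = float(rng.lognormal(-sigma2 / 2, np.sqrt(sigma2)))
            rate = config.arm_effect[arm] * config.sham_sqrt_growth_mm_per_year * mult
            for month in config.visit_months:
                s = s0 + rate * month / 12
                s_meas = max(0.0, s + rng.normal(0.0, config.sqrt_noise_sd_mm))
                rows.append(
                    {
                        "eye_id": f"{arm}-{eye_index:03d}",
                        "arm": arm,
                        "visit_month": month,
                        "feature": "RORA",
                        "area_mm2": s_meas**2,
                    }
                )
    return pd.DataFrame(rows)


def write_cohort(
    groups: list[list[SegmentationVolume]],
    truth: GroundTruth,
    out_dir: Path | str,
    overwrite: bool = False,
) -> Path:
    """Write the cohort in the on-disk dialect; returns the manifest path.

    The manifest lists every written file with its SHA-256 checksum.
    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    entries = []
    for group in groups:
        for vol in group:
            name = f"{vol.meta.eye_id}_m{vol.meta.visit_month:02d}_{vol.feature}.tif"
            path = write_volume(vol, out_dir / name)
            entries.append(
                {
                    "file": name,
                    "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                    "eye_id": vol.meta.eye_id,
                    "visit_month": vol.meta.visit_month,
                    "feature": vol.feature,
                }
            )
    truth_path = out_dir / "ground_truth.csv"
    truth.table.to_csv(truth_path, index=False)
    entries.append(
        {
            "file": truth_path.name,
            "sha256": hashlib.sha256(truth_path.read_bytes()).hexdigest(),
        }
    )
    with open(manifest_path, "w") as fh:
        json.dump({"n_volumes": len(entries) - 1, "files": entries}, fh, indent=1)
    return manifest_path
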