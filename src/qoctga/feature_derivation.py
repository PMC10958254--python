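"""En-face projection and composite-feature set algebra.

The three constituent features of geographic atrophy on OCT — RPE loss,
photoreceptor degeneration (PRD) and hypertransmission — are reduced per
A-scan to 2-D en-face maps (one row per B-scan, one column per A-scan).
Composites are pure pixelwise boolean algebra:

* RORA          = RPE loss AND PRD AND hypertransmission
* PRD isolated  = PRD AND NOT RPE loss AND NOT hypertransmission
* intact macula = ETDRS disc AND NOT (RPE loss OR PRD OR hypertransmission)

Areas are computed at the native, anisotropic B-scan grid (no resampling
in the primary endpoint); isotropic nearest-neighbour resampling is used
only for morphology and ETDRS masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CONSTITUENT_FEATURES, SegmentationVolume

COMPOSITE_FEATURES = ("RORA", "PRD_ISOLATED", "INTACT_MACULA")
ALL_FEATURES = CONSTITUENT_FEATURES + COMPOSITE_FEATURES


@dataclass
class EnFaceMapSet:
    """Registered 2-D binary rasters per feature on a common macular grid.

    ``px_spacing_mm`` is (row, col) = (slow/B-scan, fast/A-scan) spacing.
    ``fovea_px`` is (row, col) in pixel units (may be fractional).
    """

    eye_id: str
    visit_month: int
    laterality: str
    px_spacing_mm: tuple[float, float]
    fovea_px: tuple[float, float]
    maps: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.maps[feature]

    def area_mm2(self, feature: str) -> float:
        return feature_area(self.maps[feature], self.px_spacing_mm)


def project_to_enface(group: list[SegmentationVolume]) -> EnFaceMapSet:
    """Reduce the three feature volumes of one eye-visit to en-face maps.

    An en-face pixel is true iff any voxel in that A-scan's mask column is
    true.  The three volumes must share identical metadata (one acquisition).
    """
    if len(group) != 3 or {v.feature for v in group} != set(CONSTITUENT_FEATURES):
        raise ValueError(
            f"expected one volume per constituent feature {CONSTITUENT_FEATURES}"
        )
    metas = {v.meta for v in group}
    if len(metas) != 1:
        raise ValueError("constituent volumes of one eye-visit have mismatched metadata")
    meta = group[0].meta
    maps = {v.feature: v.masks.any(axis=1) for v in group}
    fx, fy = meta.fovea_xy_mm
    return EnFaceMapSet(
        eye_id=meta.eye_id,
        visit_month=meta.visit_month,
        laterality=meta.laterality,
        px_spacing_mm=(meta.bscan_spacing_mm, meta.ascan_spacing_mm),
        fovea_px=(fy / meta.bscan_spacing_mm, fx / meta.ascan_spacing_mm),
        maps=maps,
    )


def composite_masks(
    rpe_loss: np.ndarray, prd: np.ndarray, htr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """RORA and PRD-isolated rasters from the three constituent rasters."""
    if not (rpe_loss.shape == prd.shape == htr.shape):
        raise ValueError("constituent rasters must share one shape")
    rora = rpe_loss & prd & htr
    prd_isolated = prd & ~rpe_loss & ~htr
    return rora, prd_isolated


def derive_composites(constituents: EnFaceMapSet, grid) -> EnFaceMapSet:
    """Add RORA, PRD-isolated and intact-macula maps to an en-face set.

    ``grid`` is an :class:`~qoctga.etdrs.EtdrsGrid` whose raster shape and
    spacing match the constituent maps (resample first if needed).  Intact
    macula is confined to the grid's 6 mm disc by definition.
    """
    shape = constituents.shape
    if grid.disc_mask.shape != shape:
        raise ValueError(
            f"grid raster {grid.disc_mask.shape} does not match maps {shape}"
        )
    rpe, prd, htr = (constituents[f] for f in CONSTITUENT_FEATURES)
    rora, prd_iso = composite_masks(rpe, prd, htr)
    intact = grid.disc_mask & ~(rpe | prd | htr)
    maps = dict(constituents.maps)
    maps.update(RORA=rora, PRD_ISOLATED=prd_iso, INTACT_MACULA=intact)
    return EnFaceMapSet(
        eye_id=constituents.eye_id,
        visit_month=constituents.visit_month,
        laterality=constituents.laterality,
        px_spacing_mm=constituents.px_spacing_mm,
        fovea_px=constituents.fovea_px,
        maps=maps,
    )


def feature_area(mask: np.ndarray, px_spacing_mm: tuple[float, float]) -> float:
    """Area in mm² of a binary raster: true-pixel count × pixel area."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("feature rasters must be boolean")
    return float(mask.sum()) * px_spacing_mm[0] * px_spacing_mm[1]


def resample_to_isotropic(maps: EnFaceMapSet, px_mm: float = 0.01) -> EnFaceMapSet:
    """Nearest-neighbour resample of an en-face set to an isotropic grid.

    Used before morphology and ETDRS masking; the primary area endpoint
    stays on the native grid.
    """
    ry, rx = maps.px_spacing_mm
    nrow, ncol = maps.shape
    out_rows = max(1, int(round(nrow * ry / px_mm)))
    out_cols = max(1, int(round(ncol * rx / px_mm)))
    # centre-of-pixel nearest neighbour
    src_r = np.clip(((np.arange(out_rows) + 0.5) * px_mm / ry).astype(int), 0, nrow - 1)
    src_c = np.clip(((np.arange(out_cols) + 0.5) * px_mm / rx).astype(int), 0, ncol - 1)
    new_maps = {k: m[np.ix_(src_r, src_c)] for k, m in maps.maps.items()}
    fr, fc = maps.fovea_px
    return EnFaceMapSet(
        eye_id=maps.eye_id,
        visit_month=maps.visit_month,
        laterality=maps.laterality,
        px_spacing_mm=(px_mm, px_mm),
        fovea_px=(fr * ry / px_mm, fc * rx / px_mm),
        maps=new_maps,
    )
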