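"""On-disk dialect for segmentation volumes and analysis-volume selection.

A segmentation volume is stored as a multi-page TIFF (one 8-bit 0/255 page
per B-scan) with a JSON sidecar ``<stem>.meta.json`` carrying the
acquisition metadata.  One file per feature per eye-visit.  Everything
downstream assumes the coordinate convention fixed here: raster row 0 is
the superior-most B-scan, physical positions are measured in mm from the
volume's superior-temporal corner, and all indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

ARMS = ("PM", "PEOM", "SHAM")
LATERALITIES = ("OD", "OS")
CONSTITUENT_FEATURES = ("RPE_LOSS", "PRD", "HTR")

MIN_BSCANS = 25  # eligibility floor for accepted volumes


class VolumeFormatError(ValueError):
    """Raised when an on-disk volume violates the dialect contract."""


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition metadata for one eye-visit volume.

    ``fovea_xy_mm`` is (x, y) in volume coordinates: x along the fast
    (A-scan) axis, y along the slow (B-scan) axis, both from the
    superior-temporal corner.
    """

    eye_id: str
    arm: str
    visit_month: int
    laterality: str
    n_bscans: int
    ascan_spacing_mm: float
    bscan_spacing_mm: float
    fovea_xy_mm: tuple[float, float]
    field_extent_mm: tuple[float, float] = (6.0, 6.0)
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.visit_month < 0:
            raise ValueError("visit_month must be >= 0")
        if self.ascan_spacing_mm <= 0 or self.bscan_spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.n_bscans < 1:
            raise ValueError("n_bscans must be >= 1")

    @property
    def meets_bscan_minimum(self) -> bool:
        return self.n_bscans >= MIN_BSCANS

    def spans_field(self, tol: float = 0.10) -> bool:
        """Whether (n_bscans - 1) x bscan spacing covers the slow axis within ``tol``."""
        span = (self.n_bscans - 1) * self.bscan_spacing_mm
        return abs(span - self.field_extent_mm[1]) <= tol * self.field_extent_mm[1]


@dataclass
class SegmentationVolume:
    """Stack of per-B-scan binary masks for one feature of one eye-visit.

    ``masks`` has shape (n_bscans, axial, lateral), dtype bool.
    """

    meta: VolumeMeta
    feature: str
    masks: np.ndarray

    def __post_init__(self) -> None:
        if self.feature not in CONSTITUENT_FEATURES:
            raise ValueError(
                f"feature must be one of {CONSTITUENT_FEATURES}, got {self.feature!r}"
            )
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a 3-D stack (n_bscans, axial, lateral)")
        if self.masks.dtype != bool:
            raise ValueError("masks must be boolean; binarisation happens upstream")
        if self.masks.shape[0] != self.meta.n_bscans:
            raise VolumeFormatError(
                f"stack length {self.masks.shape[0]} != meta.n_bscans {self.meta.n_bscans}"
            )


def sidecar_for(path: Path | str) -> Path:
    path = Path(path)
    return path.parent / (path.stem + ".meta.json")


def _meta_to_dict(meta: VolumeMeta, feature: str) -> dict:
    d = asdict(meta)
    d["fovea_xy_mm"] = list(meta.fovea_xy_mm)
    d["field_extent_mm"] = list(meta.field_extent_mm)
    d["feature"] = feature
    return d


def _meta_from_dict(d: dict) -> tuple[VolumeMeta, str]:
    d = dict(d)
    feature = d.pop("feature")
    d["fovea_xy_mm"] = tuple(d["fovea_xy_mm"])
    d["field_extent_mm"] = tuple(d["field_extent_mm"])
    return VolumeMeta(**d), feature


def write_volume(volume: SegmentationVolume, path: Path | str) -> Path:
    """Write one feature volume as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = (volume.masks.astype(np.uint8) * 255)
    tifffile.imwrite(path, pages, compression="deflate", photometric="minisblack")
    sidecar = sidecar_for(path)
    with open(sidecar, "w") as fh:
        json.dump(_meta_to_dict(volume.meta, volume.feature), fh, indent=1, sort_keys=True)
    return path


def read_volume(path: Path | str) -> SegmentationVolume:
    """Read a multi-page TIFF + ``<stem>.meta.json`` sidecar into a :class:`SegmentationVolume`.

    Raises :class:`VolumeFormatError` for a missing sidecar, a page-count
    mismatch against ``n_bscans``, or non-binary pixel values (the offending
    page is named).
    """
    path = Path(path)
    sidecar = sidecar_for(path)
    if not sidecar.exists():
        raise VolumeFormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta, feature = _meta_from_dict(json.load(fh))
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single-page TIFF collapses the stack axis
        pages = pages[None]
    if pages.shape[0] != meta.n_bscans:
        raise VolumeFormatError(
            f"{path}: TIFF has {pages.shape[0]} pages but sidecar n_bscans={meta.n_bscans}"
        )
    for i, page in enumerate(pages):
        bad = ~np.isin(page, (0, 255))
        if bad.any():
            raise VolumeFormatError(
                f"{path}: page {i} contains non-binary pixel values "
                f"(e.g. {page[bad][0]}); masks must be 0/255"
            )
    return SegmentationVolume(meta=meta, feature=feature, masks=pages == 255)


def select_analysis_volume(
    candidates: Sequence[Sequence[SegmentationVolume]],
) -> Sequence[SegmentationVolume]:
    """Pick the acquisition to analyse for one eye-visit.

    ``candidates`` holds groups, each group being the feature volumes of a
    single acquisition.  The group with the highest B-scan count wins; ties
    are broken by the lexicographically smallest acquisition identifier so
    the choice is order-independent.
    """
    if not candidates:
        raise ValueError("no candidate volume groups for this eye-visit")
    for group in candidates:
        if not group:
            raise ValueError("candidate group is empty")
        n = {v.meta.n_bscans for v in group}
        if len(n) != 1:
            raise ValueError("volumes within one acquisition disagree on n_bscans")
    return min(
        candidates,
        key=lambda g: (-g[0].meta.n_bscans, g[0].meta.acquisition_id),
    )


def filter_eligible(
    groups: Sequence[Sequence[SegmentationVolume]],
) -> tuple[list[Sequence[SegmentationVolume]], list[Sequence[SegmentationVolume]]]:
    """Split acquisition groups into (eligible, excluded) by the 25-B-scan floor."""
    eligible = [g for g in groups if g[0].meta.meets_bscan_minimum]
    excluded = [g for g in groups if not g[0].meta.meets_bscan_minimum]
    return eligible, excluded
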