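"""End-to-end quantification: cohort directory → tidy endpoint tables.

For each eye: read the feature volumes of every visit (picking the
acquisition with the most B-scans when several exist), project to en-face
maps, resample isotropically, derive composite features on a
fovea-centred ETDRS grid, register the visit series to baseline, and
emit three tables — the per-eye-visit-feature long table (areas at the
native B-scan grid where possible), per-region ETDRS metrics and RORA
lesion morphometrics.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from .etdrs import build_etdrs_grid, region_metrics
from .feature_derivation import (
    composite_masks,
    derive_composites,
    feature_area,
    project_to_enface,
    resample_to_isotropic,
)
from .io_formats import (
    CONSTITUENT_FEATURES,
    SegmentationVolume,
    filter_eligible,
    read_volume,
    select_analysis_volume,
)
from .lesion_morphology import lesion_morphology, register_timepoints
from .trial_endpoints import build_long_table

ISO_PX_MM = 0.01


def load_cohort_dir(in_dir: Path | str) -> dict[str, dict[int, list[list[SegmentationVolume]]]]:
    """Group the TIFF volumes of a cohort directory by eye and visit.

    Volumes sharing an acquisition id form one candidate group; groups
    below the 25-B-scan eligibility floor are dropped.
    """
    in_dir = Path(in_dir)
    acq: dict[tuple, dict[str, SegmentationVolume]] = defaultdict(dict)
    for tif in sorted(in_dir.glob("*.tif")):
        vol = read_volume(tif)
        key = (vol.meta.eye_id, vol.meta.visit_month, vol.meta.acquisition_id)
        acq[key][vol.feature] = vol
    eyes: dict[str, dict[int, list]] = defaultdict(lambda: defaultdict(list))
    for (eye_id, month, _), feats in acq.items():
        if set(feats) != set(CONSTITUENT_FEATURES):
            raise ValueError(
                f"eye {eye_id} month {month}: incomplete feature set {sorted(feats)}"
            )
        eyes[eye_id][month].append([feats[f] for f in CONSTITUENT_FEATURES])
    for eye_id in eyes:
        for month in eyes[eye_id]:
            eligible, _ = filter_eligible(eyes[eye_id][month])
            eyes[eye_id][month] = eligible
    return eyes


def quantify_eye(
    visit_groups: dict[int, list[list[SegmentationVolume]]],
    refine_registration: bool = True,
) -> tuple[list[dict], pd.DataFrame, list[dict]]:
    """Quantify one eye's visit series; returns (area rows, region table, morphology rows)."""
    native = {}
    iso = []
    for month in sorted(visit_groups):
        group = select_analysis_volume(visit_groups[month])
        maps = project_to_enface(group)
        native[month] = maps
        iso.append(resample_to_isotropic(maps, ISO_PX_MM))

    # composites on the isotropic grid (per-visit grid at the recorded fovea)
    with_composites = []
    for maps in iso:
        grid = build_etdrs_grid(
            maps.shape, ISO_PX_MM, maps.fovea_px, maps.laterality
        )
        with_composites.append(derive_composites(maps, grid))
    reg = register_timepoints(with_composites, refine=refine_registration)

    # consensus-fovea grid for topography; recompute intact macula on it
    consensus_grid = build_etdrs_grid(
        reg.series[0].shape, ISO_PX_MM, reg.consensus_fovea_px, reg.series[0].laterality
    )
    area_rows, region_frames, morph_rows = [], [], []
    for maps_iso in reg.series:
        month = maps_iso.visit_month
        maps_iso = derive_composites(maps_iso, consensus_grid)
        nat = native[month]
        rpe, prd, htr = (nat[f] for f in CONSTITUENT_FEATURES)
        rora_nat, prd_iso_nat = composite_masks(rpe, prd, htr)
        sp = nat.px_spacing_mm
        # primary areas at the native anisotropic grid; intact macula needs
        # the ETDRS disc and therefore lives on the isotropic raster
        areas = {
            "RPE_LOSS": feature_area(rpe, sp),
            "PRD": feature_area(prd, sp),
            "HTR": feature_area(htr, sp),
            "RORA": feature_area(rora_nat, sp),
            "PRD_ISOLATED": feature_area(prd_iso_nat, sp),
            "INTACT_MACULA": maps_iso.area_mm2("INTACT_MACULA"),
        }
        meta = visit_groups[month][0][0].meta
        for feature, area in areas.items():
            area_rows.append(
                {
                    "eye_id": nat.eye_id,
                    "arm": meta.arm,
                    "visit_month": month,
                    "feature": feature,
                    "area_mm2": area,
                }
            )
        rm = region_metrics(maps_iso, consensus_grid).table
        rm.insert(0, "eye_id", nat.eye_id)
        rm.insert(1, "arm", meta.arm)
        rm.insert(2, "visit_month", month)
        region_frames.append(rm)
        morph = lesion_morphology(maps_iso["RORA"], (ISO_PX_MM, ISO_PX_MM))
        morph_rows.append(
            {
                "eye_id": nat.eye_id,
                "arm": meta.arm,
                "visit_month": month,
                "focality": morph.focality,
                "perimeter_mm": morph.perimeter_mm,
                "total_area_mm2": morph.total_area_mm2,
            }
        )
    return area_rows, pd.concat(region_frames, ignore_index=True), morph_rows


def quantify_cohort(
    in_dir: Path | str, refine_registration: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Quantify every eye in a cohort directory.

    Returns (long_table, region_table, morphology_table); the long table
    already carries √area and change-from-baseline columns.
    """
    eyes = load_cohort_dir(in_dir)
    area_rows, region_frames, morph_rows = [], [], []
    for eye_id in sorted(eyes):
        a, r, m = quantify_eye(eyes[eye_id], refine_registration)
        area_rows.extend(a)
        region_frames.append(r)
        morph_rows.extend(m)
    long_table = build_long_table(pd.DataFrame(area_rows))
    return long_table, pd.concat(region_frames, ignore_index=True), pd.DataFrame(morph_rows)
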