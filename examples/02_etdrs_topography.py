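"""ETDRS topography: region masks and percent occupancy.

Builds the fovea-centred ETDRS grid (1/3/6 mm circles, nine subfields) on
a 0.01 mm isotropic raster, places a 7.00 mm² circular lesion — the mean
baseline RORA size of the source trial population — and prints per-region
occupancy.
"""

import numpy as np

from qoctga import EnFaceMapSet, build_etdrs_grid, region_metrics

n, px = 601, 0.01
center = ((n - 1) / 2, (n - 1) / 2)
grid = build_etdrs_grid((n, n), px, center, laterality="OD")

print(f"6 mm disc area:        {grid.disc_mask.sum() * px**2:7.2f} mm² (π·3² = {np.pi * 9:.2f})")
print(f"central subfield area: {grid.region_area_mm2(1):7.3f} mm² (π·0.5² = {np.pi * 0.25:.3f})")

# exactly 7.00 mm²: the 70 000 pixels closest to the fovea
yy, xx = np.mgrid[0:n, 0:n]
order = np.argsort(((yy - center[0]) ** 2 + (xx - center[1]) ** 2).ravel(), kind="stable")
lesion = np.zeros((n, n), bool)
lesion.ravel()[order[:70_000]] = True

maps = EnFaceMapSet(
    eye_id="demo", visit_month=0, laterality="OD",
    px_spacing_mm=(px, px), fovea_px=center, maps={"RORA": lesion},
)
metrics = region_metrics(maps, grid)
print()
print(metrics.table[metrics.table.region_kind != "subfield"]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print(
    "A 7.00 mm² lesion occupies"
    f" {metrics.occupancy('RORA', 'disc_6mm'):.1f}% of the 6 mm disc;"
    " occupancy is 100 × lesion area within region / region area."
)
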