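"""Getis-Ord hotspot maps of Ki67+ nuclei and their axial polarisation.

Grids the segmented Ki67+ centroids (scale d = 250 full-resolution px
= 56.9 um), computes per-cell z-scores, flags hotspots at Z >= 1.96 and
measures the fraction of hotspot cells on the leading half of the lobule
growth axis.  A flat-gradient control field shows the index collapsing
to ~0.5.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mamspat import hotspot as hs
from mamspat import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1
CELL_PX = 12.5  # 50 full-scale px on the quarter-scale field
D_PX = 62.5  # 250 full-scale px = 56.9 um


def analyse(gt, label):
    cells = gt.cells
    pos = cells[
        cells.ki67 & cells.cell_class.isin(["luminal", "basal"])
    ].assign(phenotype="ki67_pos")
    grid = hs.grid_discretise(pos, gt.field_shape, CELL_PX, "ki67_pos")
    res = hs.getis_ord(grid, D_PX)
    hot = hs.hotspot_mask(res, 1.96)
    u = hs.grid_axis_coordinates(grid, gt.lobules)
    sel = hot.ravel() & np.isfinite(u.ravel())
    index = float(np.mean(u.ravel()[sel] > 0.5))
    print(
        f"{label}: {int(hot.sum())} hotspot cells of {grid.n_cells}, "
        f"polarisation index {index:.3f}"
    )
    frame = res.to_frame()
    frame["hotspot"] = hot.ravel()
    frame["axis_u"] = u.ravel()
    return frame, dict(field=label, n_hotspots=int(hot.sum()),
                       polarisation_index=index)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for label, slope in (("young_gradient", 4.0), ("flat_control", 0.0)):
        cfg = syn.SimulationConfig(seed=SEED, ki67_slope=slope)
        gt = syn.generate_field(cfg, "young")
        frame, row = analyse(gt, label)
        frame.to_csv(RESULTS / f"getis_ord_{label}.csv", index=False)
        rows.append(row)
    pd.DataFrame(rows).to_csv(RESULTS / "polarisation.csv", index=False)


if __name__ == "__main__":
    main()
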