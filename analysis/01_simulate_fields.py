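"""Generate the study's synthetic image fields and measurement tables.

Creates one render-scale H-DAB field per age group (young = < 2 months,
old = peri-pubertal), one slide-scale morphometry field, and the per-animal
measurement table (7 young + 6 old animals).  Images and masks go under
scratch/ (large, regenerable); the cell tables and the animal table go under
results/.
"""

from pathlib import Path

import yaml

from mamspat import synthetic as syn
from mamspat.core import write_image

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "fields"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for age_group in ("young", "old"):
        cfg = syn.SimulationConfig(seed=SEED)
        gt = syn.generate_field(cfg, age_group)
        field, labels = syn.render_field(gt)
        out = SCRATCH / age_group
        out.mkdir(exist_ok=True)
        write_image(out / "field.tif", field.rgb)
        write_image(out / "epithelium_truth.tif",
                    gt.epithelium_mask.astype("uint8") * 255)
        for name, lab in labels.items():
            write_image(out / f"{name}_labels.tif", lab.astype("uint16"))
        gt.cells.to_csv(RESULTS / f"cells_{age_group}.csv", index=False)
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump({"seed": SEED, "age_group": age_group,
                            "n_cells": int(len(gt.cells))}, fh)
        epi = gt.cells_of("luminal", "basal")
        print(
            f"{age_group}: {len(gt.cells)} cells "
            f"({len(epi)} epithelial, Ki67+ fraction {epi.ki67.mean():.3f})"
        )

    slide = syn.generate_field(syn.slide_scale_config(seed=SEED + 1), "young")
    slide.cells.to_csv(RESULTS / "cells_slide.csv", index=False)
    print(f"slide-scale field: {len(slide.cells)} cells, "
          f"{len(slide.ducts)} ducts")

    table = syn.emulate_measurement_tables((7, 6), seed=SEED)
    table.to_csv(RESULTS / "animal_table.csv", index=False)
    print(f"animal table: {table.animal_id.nunique()} animals, "
          f"{table.measure.nunique()} measures")


if __name__ == "__main__":
    main()
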