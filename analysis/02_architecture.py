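#!/usr/bin/env python
"""Tabulate the model architectures and probe-stage arithmetic.

Writes per-channel and total unit counts of the four early-vision variants
and the flattened feature counts at the five probe cut points to
results/architecture/, and kernel mosaics of the finest Gabor and DoG
channels to scratch/figures/.
"""

from pathlib import Path

import pandas as pd
from PIL import Image

from earlyvis import filterbank as fb
from earlyvis import models as md
from earlyvis.probe import stage_feature_counts

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "architecture"
FIG = ROOT / "scratch" / "figures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    FIG.mkdir(parents=True, exist_ok=True)

    rows = []
    for variant in md.VARIANTS:
        per, total = md.unit_count(md.make_model(variant))
        rows.append({"variant": variant, "F0": per[0], "F1": per[1],
                     "F2": per[2], "F3": per[3], "total": total})
    units = pd.DataFrame(rows)
    units.to_csv(OUT / "unit_counts.csv", index=False)
    print("Model unit counts (per spatial-frequency channel):")
    print(units.to_string(index=False))

    spec = stage_feature_counts()
    stages = pd.DataFrame({"stage": [f"C{i}" for i in range(1, 6)],
                           "cut_after_layer": spec.cut_points,
                           "flattened_features": spec.feature_counts})
    stages.to_csv(OUT / "probe_stage_counts.csv", index=False)
    print("\nProbe-stage flattened feature counts:")
    print(stages.to_string(index=False))

    for family in ("gabor", "dog"):
        bank = fb.build_bank(family)
        mosaic = fb.render_kernel_mosaic(bank, channel=3)
        Image.fromarray(mosaic, mode="L").save(FIG / f"{family}_kernels_f3.png")
    print(f"\nKernel mosaics under {FIG}")


if __name__ == "__main__":
    main()
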