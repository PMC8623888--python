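"""Simulate a 90-run granulation campaign and summarise it per impeller speed.

Draws per-granule lognormal size samples anchored to the reference size
surface for every run of a 5 x 3 x 6 design, classifies them into
fine / yield / coarse fractions (volume-weighted, 0.4 and 3 mm cuts),
computes the class-histogram mean size, and writes:

* results/batch_records.csv  - one row per simulated batch
* results/box_summary.csv    - box-chart statistics per impeller speed
"""

from pathlib import Path

import numpy as np
import pandas as pd

from granmorph import granulometry as gran, synthetic as syn

SEED = 23
GRANULES_PER_BATCH = 500
DISPERSION = 1.5  # geometric sd of the per-batch size distribution

OUT_RECORDS = Path("results/batch_records.csv")
OUT_BOX = Path("results/box_summary.csv")


def main() -> None:
    design = syn.ExperimentDesign(replicates=6, seed=SEED)
    table = syn.simulate_experiment_table(design)

    records = []
    for i, row in table.iterrows():
        diam = syn.simulate_granule_size_sample(
            row.ls_ratio, row.impeller_rpm,
            n=GRANULES_PER_BATCH, dispersion=DISPERSION, seed=SEED * 1000 + i,
        )
        fine, yld, coarse = gran.classify_granules(diam)
        # Number weights: the generator anchors the arithmetic mean, so the
        # class-histogram mean must be number-weighted to estimate it.
        hist = gran.build_histogram(
            diam, weights=np.ones_like(diam), bin_width=0.1
        )
        records.append(
            {
                "batch_id": row.batch_id,
                "ls_ratio": row.ls_ratio,
                "impeller_rpm": row.impeller_rpm,
                "replicate": row.replicate,
                "fine_pct": fine,
                "yield_pct": yld,
                "coarse_pct": coarse,
                "d_mean_mm": gran.mean_granule_size(hist),
                "d_mean_surface_mm": row.d_mean_mm,
                "yield_process_pct": row.yield_pct,
            }
        )
    records = pd.DataFrame(records)
    OUT_RECORDS.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(OUT_RECORDS, index=False)

    summaries = []
    for col in ("d_mean_mm", "yield_process_pct"):
        s = gran.box_summary(records, value_col=col)
        s.insert(0, "response", col)
        summaries.append(s)
    box = pd.concat(summaries, ignore_index=True)
    box.to_csv(OUT_BOX, index=False)

    print(f"batch records -> {OUT_RECORDS} ({len(records)} runs)")
    print(f"box summary   -> {OUT_BOX}")
    print(box.round(3).to_string(index=False))
    print(
        "\nClass-histogram mean vs the noisy surface draw differs by at most "
        f"{(records.d_mean_mm - records.d_mean_surface_mm).abs().max():.3f} mm "
        f"({GRANULES_PER_BATCH} granules per batch, geometric sd {DISPERSION})."
    )


if __name__ == "__main__":
    main()
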