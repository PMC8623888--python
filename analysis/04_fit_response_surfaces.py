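"""Fit the quadratic response surfaces to the simulated campaign.

Refits the six-term quadratic model of mean granule size and process yield
on the 90-run table from 03 (regenerated if absent), prints the recovered
coefficients next to the reference surfaces they were simulated from, runs
the per-term ANOVA and writes:

* results/model_d_mean.json / results/model_yield.json  - coefficients + ANOVA
* results/grid_d_mean.csv / results/grid_yield.csv      - coarse prediction grids
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

from granmorph import rsm

GRID_N = 21  # coarse grid for the tracked tables; the CLI writes 101 x 101

OUT_DIR = Path("results")


def main() -> None:
    records_path = OUT_DIR / "batch_records.csv"
    if not records_path.exists():
        spec = importlib.util.spec_from_file_location(
            "batch_statistics", Path(__file__).with_name("03_batch_statistics.py")
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.main()
    records = pd.read_csv(records_path)

    X = rsm.build_design_matrix(records.ls_ratio, records.impeller_rpm)
    reference = rsm.reference_models()
    for response, col in (("d_mean", "d_mean_mm"), ("yield", "yield_process_pct")):
        model = rsm.fit_quadratic(X, records[col])
        anova = rsm.anova_quadratic(model, X, records[col])
        payload = model.to_dict()
        payload["anova"] = [
            {"term": r.term, "SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p}
            for r in anova
        ]
        (OUT_DIR / f"model_{response}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        ls_grid, is_grid = rsm.default_prediction_grid(n=GRID_N)
        rsm.predict_surface(model, ls_grid, is_grid).to_csv(
            OUT_DIR / f"grid_{response}.csv", index=False
        )

        comparison = pd.DataFrame(
            {
                "term": rsm.TERM_NAMES,
                "fitted": model.coefficients,
                "reference": reference[response].coefficients,
            }
        )
        print(f"\n=== {response} surface (R^2 = {model.r_squared:.4f}) ===")
        print(comparison.to_string(index=False))
        print(rsm.anova_table(anova).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
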