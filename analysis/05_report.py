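"""Collate the campaign into a short report with contour figures.

Reads the tables written by steps 02-04, writes results/summary.md and puts
contour plots of both fitted surfaces (binary imagery) under
scratch/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

RESULTS = Path("results")
FIGURES = Path("scratch/figures")


def contour(response: str, label: str) -> Path:
    grid = pd.read_csv(RESULTS / f"grid_{response}.csv")
    n = grid.ls_ratio.nunique()
    ll = grid.ls_ratio.to_numpy().reshape(n, -1)
    ii = grid.impeller_rpm.to_numpy().reshape(n, -1)
    zz = grid.prediction.to_numpy().reshape(n, -1)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(ll, ii, zz, levels=12, cmap="viridis")
    fig.colorbar(cs, ax=ax, label=label)
    ax.set_xlabel("L/S ratio (-)")
    ax.set_ylabel("impeller speed (rpm)")
    ax.set_title(f"fitted {response} surface")
    path = FIGURES / f"contour_{response}.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def main() -> None:
    FIGURES.mkdir(parents=True, exist_ok=True)
    lines = ["# Simulated granulation campaign - summary\n"]

    morph = pd.read_csv(RESULTS / "morphology.csv")
    lines.append(
        f"Measured {len(morph)} synthetic granules; mean sphericity "
        f"{morph.sphericity.mean():.3f}, mean aspect ratio "
        f"{morph.aspect_ratio.mean():.3f}, mean concavity {morph.concavity.mean():.4f}.\n"
    )

    records = pd.read_csv(RESULTS / "batch_records.csv")
    lines.append(
        f"Simulated {len(records)} batches over L/S {records.ls_ratio.min():.2f}-"
        f"{records.ls_ratio.max():.2f} and {sorted(records.impeller_rpm.unique())} rpm; "
        f"median yield {records.yield_pct.median():.1f} %.\n"
    )

    for response in ("d_mean", "yield"):
        payload = json.loads((RESULTS / f"model_{response}.json").read_text())
        lines.append(
            f"Refitted {response} surface: R^2 = {payload['r_squared']:.4f}; "
            f"coefficients {payload['coefficients']}.\n"
        )
        fig_path = contour(response, response)
        lines.append(f"Contour figure: {fig_path}\n")

    out = RESULTS / "summary.md"
    out.write_text("\n".join(lines))
    print("\n".join(lines))
    print(f"summary -> {out}")


if __name__ == "__main__":
    main()
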