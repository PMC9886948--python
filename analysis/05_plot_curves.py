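#!/usr/bin/env python
"""Plot the optimization (Pareto) curves for all cases and modes.

Reads the per-case curve CSVs written by 03_optimize_montages.py and draws
minimum-current vs ROI-coverage curves (TER>0 gray, TER>1 black; solid
intracranial, dashed transcranial) with the conventional 0.9 A level marked.
Figures go to scratch/figures/ (binary artifacts).
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from ttfsim.pipeline import CONVENTIONAL_CURRENT_A, TUMOR_PRESETS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"

STYLES = {
    ("TER>0", "intracranial"): dict(color="0.5", ls="-"),
    ("TER>1", "intracranial"): dict(color="k", ls="-"),
    ("TER>0", "transcranial"): dict(color="0.5", ls="--"),
    ("TER>1", "transcranial"): dict(color="k", ls="--"),
}


def main() -> int:
    FIGURES.mkdir(parents=True, exist_ok=True)
    cases = list(TUMOR_PRESETS)
    fig, axes = plt.subplots(1, len(cases), figsize=(5 * len(cases), 4), sharey=True)
    for ax, case in zip(axes, cases):
        for mode in ("intracranial", "transcranial"):
            path = RESULTS / f"pareto_{case}_{mode}.csv"
            if not path.exists():
                print(f"missing {path}; run 03_optimize_montages.py first")
                return 1
            df = pd.read_csv(path)
            for crit, grp in df.groupby("criterion"):
                ax.plot(
                    grp["percent"],
                    grp["min_current_a"],
                    label=f"{crit} {mode}",
                    **STYLES[(crit, mode)],
                )
        ax.axhline(CONVENTIONAL_CURRENT_A, color="tab:blue", lw=0.8)
        ax.set_title(f"{case} tumor")
        ax.set_xlabel("ROI coverage (%)")
        ax.set_ylim(0, 2.05)
    axes[0].set_ylabel("minimum current (A)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    out = FIGURES / "optimization_curves.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
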