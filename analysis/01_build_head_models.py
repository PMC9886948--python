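#!/usr/bin/env python
"""Build the three synthetic tumor head models and check their geometry.

For each case (superficial tumor with resection cavity, deep central tumor
with core, inferior tumor) this builds the layered-sphere head, embeds the
tumor, assigns conductivities, and writes compartment volumes against the
analytic sphere values. Meshes go to scratch/ (large), the volume table to
results/head_model_volumes.csv.
"""

import math
import sys
from pathlib import Path

import pandas as pd

import ttfsim
from ttfsim import mesh_io
from ttfsim.pipeline import TUMOR_PRESETS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "head_models"


def sphere_volume(r):
    return 4.0 / 3.0 * math.pi * r**3


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    radii = ttfsim.meshing.DEFAULT_LAYER_RADII
    analytic = {
        "skin": sphere_volume(92) - sphere_volume(86),
        "skull_compact": sphere_volume(86) - sphere_volume(80),
        "csf": sphere_volume(80) - sphere_volume(78),
        "gm": sphere_volume(78) - sphere_volume(60),
        "wm": sphere_volume(60),
    }
    for case, spec in TUMOR_PRESETS.items():
        mesh = ttfsim.build_layered_sphere_mesh(
            radii,
            resolution=7.0,
            refine_spheres=[(spec.center, r) for _, r in spec.nested_parts],
        )
        mesh = ttfsim.assign_conductivity(ttfsim.embed_tumor(mesh, spec))
        mesh_io.write_vtu(mesh, SCRATCH / f"head_{case}.vtu")
        mesh_io.write_msh(mesh, SCRATCH / f"head_{case}.msh")
        lv = mesh.label_volumes()
        tumor_parts = dict(spec.nested_parts)
        for label, vol in sorted(lv.items()):
            if label in ("tumor_shell", "tumor_core", "resection"):
                # analytic part volume = its ball minus the nested inner balls
                radii_sorted = sorted(tumor_parts.values())
                r_out = tumor_parts[label]
                inner = [r for r in radii_sorted if r < r_out]
                exact = sphere_volume(r_out) - (sphere_volume(inner[-1]) if inner else 0.0)
            else:
                exact = analytic.get(label, float("nan"))
            rows.append(
                {
                    "case": case,
                    "tissue": label,
                    "mesh_volume_mm3": round(vol, 1),
                    "analytic_volume_mm3": round(exact, 1),
                    "relative_error_percent": round(100 * (vol - exact) / exact, 2)
                    if exact == exact
                    else float("nan"),
                }
            )
        print(
            f"{case}: {len(mesh.nodes)} nodes, {len(mesh.elements)} elements, "
            f"tumor {sum(v for k, v in lv.items() if k.startswith('tumor')):.0f} mm^3"
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "head_model_volumes.csv", index=False)
    print(f"\nwrote {RESULTS / 'head_model_volumes.csv'}")
    print(df.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
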