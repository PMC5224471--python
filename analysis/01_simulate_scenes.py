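#!/usr/bin/env python
"""Generate the synthetic scene battery used throughout the analysis.

Writes a small, representative set of two-channel scenes spanning true
co-location fractions 0, 0.5 and 1 as OME-TIFF stacks, together with a
ground-truth CSV (punctum centers in nm, co-location flags) and a manifest
the downstream scripts consume.  Larger batteries are regenerated on the
fly by the scripts that need them — scenes are cheap to simulate and fully
determined by their seed.
"""

from pathlib import Path

import pandas as pd

from vesicoloc import save_stack, scene_battery
from vesicoloc.synthetic_scenes import SyntheticSceneSpec

OUT = Path("results/scenes")
FRACTIONS = [0.0, 0.5, 1.0]
N_REPS = 3
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_rows, manifest_rows = [], []
    scenes = scene_battery(
        FRACTIONS, N_REPS, base_spec=SyntheticSceneSpec(min_sep_scope="all"),
        seed=SEED,
    )
    for i, (spec, stack, truth) in enumerate(scenes):
        name = f"scene_{i:02d}_f{spec.coloc_fraction:.2f}.ome.tif"
        save_stack(stack.replace(cell_id=f"scene{i:02d}"), OUT / name)
        manifest_rows.append(
            {"file": str(OUT / name), "time_min": 0.0,
             "condition": f"f={spec.coloc_fraction:.2f}", "cell_id": f"scene{i:02d}"}
        )
        first = spec.channels[spec.coloc_channels[0]].name
        for ch_name, centers in truth.centers_nm.items():
            co = {
                (pa if ch_name == first else pb)
                for pa, pb in truth.coloc_pairs
            } if ch_name in (first, spec.channels[spec.coloc_channels[1]].name) else set()
            for j, (y, x) in enumerate(centers):
                truth_rows.append(
                    {"file": name, "channel": ch_name, "punctum": j,
                     "y_nm": round(float(y), 2), "x_nm": round(float(x), 2),
                     "z": int(truth.z_index[ch_name][j]), "colocated": j in co}
                )
    pd.DataFrame(truth_rows).to_csv(OUT / "ground_truth.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(OUT / "manifest.csv", index=False)
    print(f"wrote {len(scenes)} scenes, ground truth and manifest under {OUT}/")


if __name__ == "__main__":
    main()
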