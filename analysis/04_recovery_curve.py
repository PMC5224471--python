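#!/usr/bin/env python
"""Measure how the pipeline's percent tracks the true co-location fraction.

Runs a scene battery over true fractions {0, 0.25, 0.5, 0.75, 1.0} (20
replicates each at SNR ~10), measures the whole-cell pixel-overlap percent
and the object-level (centroid-matched) fraction per scene, and writes the
per-scene table plus a per-fraction summary.  The headline checks: the mean
measured percent increases strictly with the true fraction, the endpoints
behave (f=0 below 2%, f=1 above 90%), and object-level recovery errs by
0.1 or less on average.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vesicoloc import DOGParams, auto_threshold, cell_coloc, dog_filter, global_threshold
from vesicoloc.synthetic_scenes import (
    SyntheticSceneSpec,
    battery_specs,
    object_coloc_fraction,
    simulate_scene,
)

OUT = Path("results")
FRACTIONS = [0.0, 0.25, 0.5, 0.75, 1.0]
N_REPS = 20
SEED = 99


def main() -> None:
    params = DOGParams()
    rows = []
    specs = battery_specs(
        FRACTIONS, N_REPS,
        base_spec=SyntheticSceneSpec(min_sep_scope="all", jitter_nm=0.0),
        seed=SEED,
    )
    for spec in specs:
        stack, _ = simulate_scene(spec)
        res = cell_coloc(stack, "cargo", "marker", params=params)
        masks = {}
        for name in ("cargo", "marker"):
            filt = dog_filter(stack.channel(name)[0], params, spec.pixel_size_nm)
            masks[name] = global_threshold(filt, auto_threshold(filt), label=name)
        rows.append(
            {
                "true_fraction": spec.coloc_fraction,
                "seed": spec.seed,
                "percent": res.percent,
                "null_percent": res.null_percent,
                "object_fraction": object_coloc_fraction(
                    masks["cargo"], masks["marker"]
                ),
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "recovery_per_scene.csv", index=False)

    summary = table.groupby("true_fraction").agg(
        mean_percent=("percent", "mean"),
        sem_percent=("percent", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
        mean_object_fraction=("object_fraction", "mean"),
        mean_null=("null_percent", "mean"),
    )
    summary.to_csv(OUT / "recovery_summary.csv")
    print(summary.to_string(float_format=lambda v: f"{v:.3f}"))
    mae = (table.object_fraction - table.true_fraction).abs().mean()
    print(f"\nobject-level recovery MAE: {mae:.3f}")
    means = summary.mean_percent.to_numpy()
    print(f"strictly increasing in f: {bool(np.all(np.diff(means) > 0))}")


if __name__ == "__main__":
    main()
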