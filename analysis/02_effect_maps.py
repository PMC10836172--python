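#!/usr/bin/env python
"""Estimate per-parcel effect maps with mass-univariate mixed models.

Step 1 of the analysis: for every parcel, a linear mixed model with a
participant random intercept estimates the effect of each psycholinguistic
parameter on trial activation, in the primary version (with word length)
and the duration-control version (presentation duration replacing length).
Writes the ten effect maps to scratch/study/maps/ and a summary (median
estimate, sign balance, singular-fit count per map) to
results/effect_maps_summary.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np

import gradlex as gx
from gradlex import io as gio
from common import RESULTS, SCRATCH, get_study


def main() -> int:
    study = get_study()
    trials = study.trials["0-100"]
    primary = gx.fit_mass_lmm(trials, study.features)
    control = gx.duration_control_refit(trials, study.features)

    mapdir = SCRATCH / "maps"
    mapdir.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    summary = {}
    for tag, maps in (("primary", primary), ("control", control)):
        for p, em in maps.items():
            gio.write_effect_map(em, study.atlas, mapdir / f"{tag}_{p}.tsv")
            vals = em.values[em.included]
            summary[f"{tag}:{p}"] = {
                "median_estimate": float(np.median(vals)),
                "frac_negative": float((vals < 0).mean()),
                "n_singular_fits": int(em.flags["ols_fallback"].sum()),
                "true_slope": study.profiles[p].slope if p in study.profiles else None,
            }
    gio.write_results(summary, RESULTS / "effect_maps_summary.json")

    for key, s in summary.items():
        print(f"{key:18s} median={s['median_estimate']:+.3f} "
              f"neg={s['frac_negative']:.2f} singular={s['n_singular_fits']}")
    print(f"wrote {RESULTS / 'effect_maps_summary.json'} and maps under {mapdir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
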