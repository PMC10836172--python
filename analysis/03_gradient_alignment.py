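#!/usr/bin/env python
"""Gradient alignment of each effect map, with spin inference and the
step-versus-linear comparison.

Steps 2 and 3 of the analysis: after sign normalization, regress each
(primary and control) effect map on gradient x hemisphere, convert the
gradient terms to spin p-values against 500 permuted gradients, apply the
both-versions significance rule, and — for associations that survive —
ask whether a three-step function beats the linear fit by more than four
AIC and BIC points.  Reads the maps written by 02 (refits them if absent)
and writes results/alignment.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import gradlex as gx
from gradlex import io as gio
from common import N_PERM, RESULTS, SCRATCH, STUDY_SEED, get_study


def load_or_fit_maps(study):
    mapdir = SCRATCH / "maps"
    params_ctrl = [p if p != "length" else "duration" for p in gx.PARAMETERS]
    try:
        primary = {p: gio.read_effect_map(mapdir / f"primary_{p}.tsv") for p in gx.PARAMETERS}
        control = {p: gio.read_effect_map(mapdir / f"control_{p}.tsv") for p in params_ctrl}
    except (FileNotFoundError, ValueError):
        trials = study.trials["0-100"]
        primary = gx.fit_mass_lmm(trials, study.features)
        control = gx.duration_control_refit(trials, study.features)
    return primary, control


def main() -> int:
    study = get_study()
    primary, control = load_or_fit_maps(study)
    atlas = study.atlas
    spins = gx.generate_spins(atlas, N_PERM, seed=STUDY_SEED + 1)
    RESULTS.mkdir(parents=True, exist_ok=True)

    out = {}
    for p in gx.PARAMETERS:
        em = gx.normalize_sign(primary[p])
        assoc = gx.spin_test_association(em, atlas, spins)
        ctrl = None
        if p != "length":
            ctrl = gx.spin_test_association(gx.normalize_sign(control[p]), atlas, spins)
        joint = gx.combine_control(assoc, ctrl)
        entry = {
            "slope": assoc.coef["gradient"],
            "t": assoc.t["gradient"],
            "p_spin": assoc.p_spin["gradient"],
            "p_spin_label": gx.format_spin_p(assoc.p_spin["gradient"], N_PERM),
            "significant_both_versions": joint["significant"],
            "sign_inverted": em.sign_inverted,
        }
        if joint["significant"]:
            comp = gx.compare_step_linear(em, atlas, k=3, spins=spins)
            entry["model_comparison"] = {
                "d_aic": comp.d_aic,
                "d_bic": comp.d_bic,
                "verdict": comp.verdict,
            }
        out[p] = entry
        verdict = entry.get("model_comparison", {}).get("verdict", "-")
        print(f"{p:9s} slope={entry['slope']:+.3f} p_spin {entry['p_spin_label']:7s} "
              f"both-versions={'yes' if joint['significant'] else 'no':3s} shape={verdict}")

    gio.write_results(out, RESULTS / "alignment.json")
    print(f"wrote {RESULTS / 'alignment.json'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
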