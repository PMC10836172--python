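"""End-to-end pipeline driver.

Chains the full three-step analysis on a study's data: effect-map
estimation (primary and duration-control model versions), sign
normalization, gradient-association regression with spin inference, the
step-versus-linear model comparison, and the dissociation ANOVAs — and
records every gate decision in a manifest so a run is reproducible from
its seed and configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import yaml

from . import io as gio
from .align import (
    combine_control,
    compare_step_linear,
    fit_gradient_model,
    normalize_sign,
    spin_test_association,
)
from .atlas import ParcelAtlas
from .config import PARAMETERS, SimConfig, TrueProfile
from .dissociation import parameter_anova, timewindow_anova
from .effects import duration_control_refit, fit_mass_lmm
from .spin import generate_spins
from .synth import SyntheticStudy, make_study

__all__ = ["PipelineConfig", "run_pipeline", "run_synthetic_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis settings for one pipeline run."""

    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    sided: str = "two"
    step_k: int = 3
    modality: str = "meg"
    ev_scheme: str = "fixed_1s"
    families: Sequence[str] = ("linear",)
    outdir: Optional[str] = None

    def validate(self, inference: bool = True) -> "PipelineConfig":
        if inference and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for inference runs")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.step_k not in (2, 3):
            raise ValueError("step_k must be 2 or 3")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(study: SyntheticStudy, config: PipelineConfig) -> dict:
    """Run the full analysis on a study with MEG-style trial data.

    Steps: per-window mass LMMs (primary, and the duration-control refit) ->
    sign normalization -> per-parameter gradient association with spin
    p-values and the both-versions rule -> step-vs-linear comparison ->
    gradient x parameter dissociation ANOVA per window (primary and
    control) -> gradient x window ANOVA per parameter when all five windows
    are present.
    """
    config.validate()
    atlas = study.atlas
    spins = generate_spins(atlas, config.n_perm, config.seed)
    manifest = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "sided": config.sided,
        "sim_config": study.config.to_dict(),
        "gates": [],
    }
    results: dict = {"associations": {}, "comparisons": {}, "dissociation": {}}

    maps_by_window: Dict[str, Dict[str, dict]] = {}
    for window, trials in study.trials.items():
        primary = fit_mass_lmm(trials, study.features)
        control = duration_control_refit(trials, study.features)
        maps_by_window[window] = {"primary": primary, "control": control}

    # step 2: gradient associations, with the duration-control rule
    control_of = {"length": None, **{p: p for p in PARAMETERS if p != "length"}}
    for window, versions in maps_by_window.items():
        results["associations"][window] = {}
        results["comparisons"][window] = {}
        for p in PARAMETERS:
            em = normalize_sign(versions["primary"][p])
            assoc = spin_test_association(
                em, atlas, spins, family="linear", sided=config.sided
            )
            ctrl_assoc = None
            if control_of[p] is not None:
                ctrl_em = normalize_sign(versions["control"][p])
                ctrl_assoc = spin_test_association(
                    ctrl_em, atlas, spins, family="linear", sided=config.sided
                )
            joint = combine_control(assoc, ctrl_assoc, alpha=config.alpha)
            manifest["gates"].append(
                {"stage": "association", "window": window, "parameter": p, **joint}
            )
            entry = {
                "primary": assoc.to_dict(),
                "control": ctrl_assoc.to_dict() if ctrl_assoc else None,
                "significant_both_versions": joint["significant"],
            }
            for fam in config.families:
                if fam != "linear":
                    entry[fam] = fit_gradient_model(em, atlas, family=fam).to_dict()
            results["associations"][window][p] = entry

            # step 3: linear-vs-step comparison for significant associations
            if joint["significant"]:
                comp = compare_step_linear(em, atlas, k=config.step_k, spins=spins)
                results["comparisons"][window][p] = comp.to_dict()
                manifest["gates"].append(
                    {
                        "stage": "model_comparison",
                        "window": window,
                        "parameter": p,
                        "verdict": comp.verdict,
                    }
                )

    # dissociation: gradient x parameter per window, both model versions
    for window, versions in maps_by_window.items():
        prim_maps = {p: normalize_sign(versions["primary"][p]) for p in PARAMETERS}
        omni = parameter_anova(prim_maps, atlas, spins, alpha=config.alpha, sided=config.sided)
        ctrl_params = [p for p in PARAMETERS if p != "length"] + ["duration"]
        ctrl_maps = {p: normalize_sign(versions["control"][p]) for p in ctrl_params}
        omni_ctrl = parameter_anova(
            ctrl_maps, atlas, spins, alpha=config.alpha, sided=config.sided
        )
        both = (
            omni.p_spin.get("gradient:level", 1.0) < config.alpha
            and omni_ctrl.p_spin.get("gradient:level", 1.0) < config.alpha
        )
        results["dissociation"][window] = {
            "primary": _interaction_dict(omni),
            "control": _interaction_dict(omni_ctrl),
            "significant_both_versions": bool(both),
        }
        manifest["gates"].append(
            {"stage": "dissociation", "window": window, "significant_both_versions": bool(both)}
        )

    # time-window dissociation per parameter, when all five windows exist
    windows = list(study.trials)
    if len(windows) == 5:
        results["dissociation"]["by_window"] = {}
        for p in PARAMETERS:
            wmaps = {
                w: normalize_sign(maps_by_window[w]["primary"][p]) for w in windows
            }
            tw = timewindow_anova(
                wmaps, atlas, spins, alpha=config.alpha, sided=config.sided, windows=windows
            )
            results["dissociation"]["by_window"][p] = _interaction_dict(tw)

    results["manifest"] = manifest
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_results(results, out / "results.json")
        gio.write_atlas(atlas, out / "atlas.csv")
    return results


def _interaction_dict(res) -> dict:
    return {
        "factor": res.factor,
        "levels": res.levels,
        "F": res.F,
        "p_param": res.p_param,
        "p_spin": res.p_spin,
        "gates": res.gates,
        "contrasts": res.contrasts,
        "n_parcels": res.n_parcels,
    }


def run_synthetic_pipeline(
    sim_config: SimConfig,
    profiles: Dict[str, TrueProfile],
    pipeline_config: Optional[PipelineConfig] = None,
    windows: Sequence[str] = ("0-100",),
) -> dict:
    """Generate a synthetic study and run the full pipeline on it."""
    if pipeline_config is None:
        pipeline_config = PipelineConfig(seed=sim_config.seed)
    study = make_study(sim_config, profiles, windows=windows)
    return run_pipeline(study, pipeline_config)
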