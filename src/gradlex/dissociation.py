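"""Dissociation of parameters (and time windows) along the gradient.

Tests whether different psycholinguistic parameters — or, for MEG-style
maps, different 100-ms time windows — occupy different gradient positions:
an omnibus ANOVA on the long-form stack of sign-normalized effect maps with
gradient x level and gradient x level x hemisphere interaction F statistics
(Type-II sums of squares), spin p-values for terms passing the parametric
screen, and the gated follow-up hierarchy (omnibus -> pairwise contrasts;
significant three-way -> per-hemisphere contrasts).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .atlas import ParcelAtlas
from .effects import EffectMap
from .spin import SpinSet, spin_pvalue

__all__ = [
    "InteractionResult",
    "parameter_anova",
    "timewindow_anova",
    "pairwise_contrast",
    "pairwise_parameter_contrast",
]

MEG_WINDOWS = ("0-100", "100-200", "200-300", "300-400", "400-500")


@dataclass
class InteractionResult:
    """Omnibus interaction ANOVA with gated pairwise follow-ups."""

    factor: str  # 'parameter' | 'window'
    levels: List[str]
    F: Dict[str, float]
    df: Dict[str, tuple]
    p_param: Dict[str, float]
    p_spin: Dict[str, float]
    contrasts: List[dict] = field(default_factory=list)
    gates: Dict[str, bool] = field(default_factory=dict)
    n_parcels: int = 0

    def level_involvement(self) -> Dict[str, int]:
        """How many significant pairwise contrasts each level takes part in."""
        counts = {lev: 0 for lev in self.levels}
        for c in self.contrasts:
            if c.get("significant"):
                counts[c["level_a"]] += 1
                counts[c["level_b"]] += 1
        return counts


# ---------------------------------------------------------------------------
# stacking and F machinery


def _stack(maps: Dict[str, EffectMap], atlas: ParcelAtlas, gradient: Optional[np.ndarray]):
    levels = list(maps)
    inc_sets = [m.included for m in maps.values()]
    inc = np.logical_and.reduce(inc_sets)
    if any((s != inc).any() for s in inc_sets):
        warnings.warn("inclusion sets differ across maps; using their intersection")
    if not inc.any():
        raise ValueError("empty intersection of included parcels")
    for m in maps.values():
        if len(m.values) != atlas.n_parcels:
            raise ValueError("effect map and atlas have different parcel counts")
    g_all = atlas.gradient if gradient is None else np.asarray(gradient, float)
    idx = np.flatnonzero(inc)
    n = len(idx)
    y = np.concatenate([maps[lev].values[idx] for lev in levels])
    g = np.tile(g_all[idx], len(levels))
    hemi = np.tile(atlas.hemi_sign()[idx], len(levels))
    level_idx = np.repeat(np.arange(len(levels)), n)
    return levels, idx, y, g, hemi, level_idx, g_all, inc


def _interaction_designs(g, hemi, level_idx, n_levels):
    """Base / +two-way / +three-way design matrices (treatment-coded levels)."""
    dummies = [(level_idx == j).astype(float) for j in range(1, n_levels)]
    base_cols = [np.ones(len(g)), g, hemi, g * hemi]
    base_cols += dummies
    base_cols += [d * hemi for d in dummies]
    base = np.column_stack(base_cols)
    two = np.column_stack(base_cols + [d * g for d in dummies])
    full = np.column_stack(
        base_cols + [d * g for d in dummies] + [d * g * hemi for d in dummies]
    )
    return base, two, full


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def _anova_f(y, g, hemi, level_idx, n_levels):
    """Type-II F for gradient x level and gradient x level x hemisphere.

    SS(gradient x level) is taken from the model hierarchy excluding the
    three-way term (which contains it); both F's share the full-model mean
    squared error as denominator.
    """
    base, two, full = _interaction_designs(g, hemi, level_idx, n_levels)
    rss_base, rss_two, rss_full = _rss(base, y), _rss(two, y), _rss(full, y)
    q = n_levels - 1
    dof_resid = len(y) - full.shape[1]
    mse = rss_full / dof_resid
    f_two = ((rss_base - rss_two) / q) / mse if mse > 0 else np.inf
    f_three = ((rss_two - rss_full) / q) / mse if mse > 0 else np.inf
    return (
        {"gradient:level": f_two, "gradient:level:hemisphere": f_three},
        {"gradient:level": (q, dof_resid), "gradient:level:hemisphere": (q, dof_resid)},
        mse,
    )


# ---------------------------------------------------------------------------
# pairwise contrasts


def pairwise_contrast(
    map_a: EffectMap,
    map_b: EffectMap,
    atlas: ParcelAtlas,
    spins: Optional[SpinSet] = None,
    gradient: Optional[np.ndarray] = None,
    scope: str = "both",
    sided: str = "two",
    labels: Optional[tuple] = None,
) -> dict:
    """Gradient x level interaction t for a two-level stack of maps.

    scope 'both' fits the bi-hemispheric model (with hemisphere terms);
    'left'/'right' restrict to one hemisphere and drop them.  A zero-
    residual stack (exactly opposite noise-free maps) is reported with a
    degenerate flag and the spin p at its floor.
    """
    inc = map_a.included & map_b.included
    if scope in ("left", "right"):
        inc = inc & (atlas.hemispheres == ("L" if scope == "left" else "R"))
    if not inc.any():
        raise ValueError("no parcels in contrast scope")
    g_all = atlas.gradient if gradient is None else np.asarray(gradient, float)
    idx = np.flatnonzero(inc)

    def stat(gv: np.ndarray) -> tuple[float, bool]:
        y = np.concatenate([map_a.values[idx], map_b.values[idx]])
        g = np.tile(gv[idx], 2)
        lev = np.repeat([0.0, 1.0], len(idx))
        cols = [np.ones(len(y)), g, lev, g * lev]
        names = ["const", "gradient", "level", "gradient:level"]
        if scope == "both":
            h = np.tile(atlas.hemi_sign()[idx], 2)
            cols += [h, g * h, lev * h, g * lev * h]
            names += ["hemi", "g:h", "l:h", "g:l:h"]
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        rss = float(resid @ resid)
        dof = len(y) - x.shape[1]
        tss = float(((y - y.mean()) ** 2).sum())
        degenerate = rss <= max(tss, 1.0) * 1e-12
        sigma2 = rss / dof
        xtx_inv = np.linalg.pinv(x.T @ x)
        j = names.index("gradient:level")
        se = np.sqrt(max(0.0, xtx_inv[j, j] * sigma2))
        return (beta[j] / se if se > 0 else np.nan), degenerate

    t_obs, degenerate = stat(g_all)
    if labels is None:
        labels = (map_a.parameter, map_b.parameter)
    out = {
        "level_a": labels[0],
        "level_b": labels[1],
        "scope": scope,
        "t": t_obs,
        "degenerate": degenerate,
    }
    if spins is not None:
        null = np.empty(spins.n_perm)
        for k in range(spins.n_perm):
            null[k], _ = stat(g_all[spins.perms[k]])
        obs = np.inf if degenerate and not np.isfinite(t_obs) else t_obs
        out["p_spin"] = spin_pvalue(
            obs, null, sided="one" if not np.isfinite(t_obs) else sided
        )
    return out


def pairwise_parameter_contrast(
    map_a: EffectMap,
    map_b: EffectMap,
    atlas: ParcelAtlas,
    spins: Optional[SpinSet] = None,
    gradient: Optional[np.ndarray] = None,
    scope: str = "both",
    sided: str = "two",
) -> dict:
    """Alias of pairwise_contrast for parameter pairs (caller enforces gating)."""
    return pairwise_contrast(map_a, map_b, atlas, spins, gradient, scope, sided)


# ---------------------------------------------------------------------------
# omnibus ANOVAs


def _interaction_anova(
    maps: Dict[str, EffectMap],
    atlas: ParcelAtlas,
    spins: Optional[SpinSet],
    factor: str,
    gradient: Optional[np.ndarray],
    alpha: float,
    sided: str,
) -> InteractionResult:
    levels, idx, y, g, hemi, level_idx, g_all, inc = _stack(maps, atlas, gradient)
    n_levels = len(levels)
    f_obs, dfs, _ = _anova_f(y, g, hemi, level_idx, n_levels)
    p_param = {
        term: float(stats.f.sf(f, *dfs[term])) for term, f in f_obs.items()
    }
    res = InteractionResult(
        factor=factor,
        levels=levels,
        F=f_obs,
        df=dfs,
        p_param=p_param,
        p_spin={},
        n_parcels=len(idx),
    )
    tested = [term for term in f_obs if p_param[term] < alpha]
    if spins is not None and tested:
        null = {term: np.empty(spins.n_perm) for term in tested}
        for k in range(spins.n_perm):
            gp = g_all[spins.perms[k]]
            g_k = np.tile(gp[idx], n_levels)
            f_k, _, _ = _anova_f(y, g_k, hemi, level_idx, n_levels)
            for term in tested:
                null[term][k] = f_k[term]
        for term in tested:
            # F statistics: large values are evidence, one-sided by construction
            res.p_spin[term] = spin_pvalue(f_obs[term], null[term], sided="one")

    omnibus_pass = res.p_spin.get("gradient:level", 1.0) < alpha
    three_way_pass = res.p_spin.get("gradient:level:hemisphere", 1.0) < alpha
    res.gates = {"omnibus": omnibus_pass, "three_way": three_way_pass}
    if omnibus_pass:
        scopes = ["both"] + (["left", "right"] if three_way_pass else [])
        for (la, lb), scope in itertools.product(
            itertools.combinations(levels, 2), scopes
        ):
            c = pairwise_contrast(
                maps[la], maps[lb], atlas, spins, gradient,
                scope=scope, sided=sided, labels=(la, lb),
            )
            c["significant"] = bool(c.get("p_spin", 1.0) < alpha)
            res.contrasts.append(c)
    return res


def parameter_anova(
    maps: Dict[str, EffectMap],
    atlas: ParcelAtlas,
    spins: Optional[SpinSet] = None,
    gradient: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    sided: str = "two",
) -> InteractionResult:
    """Gradient x parameter (x hemisphere) omnibus over five effect maps.

    Maps must be sign-normalized first so that a positive association means
    "stronger effect towards the heteromodal end" for every parameter.
    """
    if len(maps) < 2:
        raise ValueError("need at least two parameter maps")
    return _interaction_anova(maps, atlas, spins, "parameter", gradient, alpha, sided)


def timewindow_anova(
    maps: Dict[str, EffectMap],
    atlas: ParcelAtlas,
    spins: Optional[SpinSet] = None,
    gradient: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    sided: str = "two",
    windows: Sequence[str] = MEG_WINDOWS,
) -> InteractionResult:
    """Gradient x time-window (x hemisphere) omnibus for one parameter.

    Window is a discrete five-level factor; all five 100-ms windows must be
    present, each sign-normalized per window.
    """
    missing = [w for w in windows if w not in maps]
    if missing:
        raise ValueError(f"missing time windows: {missing}")
    ordered = {w: maps[w] for w in windows}
    return _interaction_anova(ordered, atlas, spins, "window", gradient, alpha, sided)
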