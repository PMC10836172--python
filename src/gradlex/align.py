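"""Gradient-alignment regression, spin inference, and model comparison.

Quantifies how an effect map depends on position along a cortical gradient:
ordinary-least-squares fits of value ~ gradient x hemisphere (linear,
quadratic, or k-step families), spin-permutation p-values for the gradient
terms, sign normalization of effect maps, and the AIC/BIC step-versus-linear
verdict with its +/-4 decision rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import stats

from .atlas import ParcelAtlas
from .effects import EffectMap
from .spin import SpinSet, spin_pvalue

__all__ = [
    "AssociationResult",
    "ModelComparison",
    "normalize_sign",
    "fit_gradient_model",
    "spin_test_association",
    "compare_step_linear",
    "verdict_from_deltas",
    "combine_control",
    "gaussian_aic_bic",
]

FAMILIES = ("linear", "quadratic", "step2", "step3")
MIN_PER_HEMI = 10


# ---------------------------------------------------------------------------
# sign normalization


def normalize_sign(em: EffectMap) -> EffectMap:
    """Invert a map when strictly more than half of included values are negative.

    Ensures that positive gradient associations always mean "stronger
    effect towards the heteromodal end" regardless of the raw effect
    direction; an exact tie leaves the map unchanged.
    """
    if em.included.sum() < 1:
        raise ValueError("no included parcels")
    out = em.copy()
    vals = em.values[em.included]
    if (vals < 0).sum() * 2 > len(vals):
        out.values = -out.values
        out.sign_inverted = not em.sign_inverted
    return out


# ---------------------------------------------------------------------------
# model designs


def _step_bins(g: np.ndarray, hemi: np.ndarray, k: int, scheme: str) -> np.ndarray:
    """Assign parcels to k gradient bins within hemisphere.

    equal_count (default): quantile cuts balance parcels per bin;
    equal_width: uniform cuts over the within-hemisphere gradient range.
    """
    bins = np.empty(len(g), dtype=int)
    for h in np.unique(hemi):
        m = hemi == h
        if scheme == "equal_count":
            edges = np.quantile(g[m], np.linspace(0, 1, k + 1)[1:-1])
        elif scheme == "equal_width":
            edges = np.linspace(g[m].min(), g[m].max(), k + 1)[1:-1]
        else:
            raise ValueError(f"unknown binning scheme {scheme!r}")
        bins[m] = np.digitize(g[m], edges)
    return bins


def _family_design(
    g: np.ndarray, hemi_pm: np.ndarray, family: str, bins: str = "equal_count"
):
    """Design matrix, column names, and metadata for one model family.

    Hemisphere is coded -0.5 (L) / +0.5 (R), so the gradient main effect is
    the mean slope across hemispheres and the interaction is the slope
    difference.  Step factors use treatment coding against the first bin.
    """
    cols = [np.ones(len(g)), hemi_pm]
    names = ["const", "hemisphere"]
    meta: Dict[str, object] = {"family": family}
    if family == "linear" or family == "quadratic":
        cols += [g, g * hemi_pm]
        names += ["gradient", "gradient:hemisphere"]
        if family == "quadratic":
            cols += [g**2, (g**2) * hemi_pm]
            names += ["gradient2", "gradient2:hemisphere"]
    elif family in ("step2", "step3"):
        k = int(family[-1])
        assign = _step_bins(g, hemi_pm, k, bins)
        meta["bins"] = assign
        meta["k"] = k
        for b in range(1, k):
            d = (assign == b).astype(float)
            cols.append(d)
            names.append(f"step{b + 1}")
        for b in range(1, k):
            cols.append((assign == b).astype(float) * hemi_pm)
            names.append(f"step{b + 1}:hemisphere")
    else:
        raise ValueError(f"unknown model family {family!r}")
    return np.column_stack(cols), names, meta


def _ols(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS: beta, se, t, dof, rss, degenerate flag."""
    n, p = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    rss = float(resid @ resid)
    dof = n - np.linalg.matrix_rank(x)
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= max(tss, 1.0) * 1e-12
    sigma2 = rss / dof if dof > 0 else np.nan
    se = np.sqrt(np.maximum(0.0, np.diag(xtx_inv)) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    return beta, se, t, dof, rss, degenerate


# ---------------------------------------------------------------------------
# association results


@dataclass
class AssociationResult:
    """Coefficients, t statistics and p-values of one gradient-model fit."""

    parameter: str
    modality: str
    window: Optional[str]
    family: str
    coef: Dict[str, float]
    se: Dict[str, float]
    t: Dict[str, float]
    p_param: Dict[str, float]
    n_parcels: int
    dof: int
    degenerate: bool
    tag: str = "primary"
    sided: str = "two"
    p_spin: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "modality": self.modality,
            "window": self.window,
            "family": self.family,
            "tag": self.tag,
            "n_parcels": self.n_parcels,
            "degenerate": self.degenerate,
            "coef": self.coef,
            "t": self.t,
            "p_param": self.p_param,
            "p_spin": self.p_spin,
        }


def _included_arrays(em: EffectMap, atlas: ParcelAtlas, gradient: Optional[np.ndarray]):
    if len(em.values) != atlas.n_parcels:
        raise ValueError("effect map and atlas have different parcel counts")
    g_all = atlas.gradient if gradient is None else np.asarray(gradient, float)
    if len(g_all) != atlas.n_parcels:
        raise ValueError("gradient map and atlas have different parcel counts")
    inc = em.included
    if not np.isfinite(g_all[inc]).all():
        raise ValueError("gradient undefined for included parcels")
    hemi_pm = atlas.hemi_sign()
    for h in (-0.5, 0.5):
        if (hemi_pm[inc] == h).sum() < MIN_PER_HEMI:
            raise ValueError(f"need >= {MIN_PER_HEMI} included parcels per hemisphere")
    return em.values[inc], g_all[inc], hemi_pm[inc], g_all, inc


def fit_gradient_model(
    em: EffectMap,
    atlas: ParcelAtlas,
    family: str = "linear",
    gradient: Optional[np.ndarray] = None,
    bins: str = "equal_count",
) -> AssociationResult:
    """Least-squares fit of value ~ family(gradient) x hemisphere."""
    y, g, hemi, _, _ = _included_arrays(em, atlas, gradient)
    x, names, _ = _family_design(g, hemi, family, bins)
    beta, se, t, dof, _, degenerate = _ols(x, y)
    p = 2.0 * stats.t.sf(np.abs(t), df=max(dof, 1))
    return AssociationResult(
        parameter=em.parameter,
        modality=em.modality,
        window=em.window,
        family=family,
        coef=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        t=dict(zip(names, t)),
        p_param=dict(zip(names, p)),
        n_parcels=len(y),
        dof=dof,
        degenerate=degenerate,
        tag=em.tag,
    )


def _term_t(
    y: np.ndarray, g: np.ndarray, hemi: np.ndarray, family: str, bins: str, terms: List[str]
) -> Dict[str, float]:
    x, names, _ = _family_design(g, hemi, family, bins)
    _, _, t, _, _, _ = _ols(x, y)
    lut = dict(zip(names, t))
    return {term: lut[term] for term in terms}


def spin_test_association(
    em: EffectMap,
    atlas: ParcelAtlas,
    spins: SpinSet,
    family: str = "linear",
    gradient: Optional[np.ndarray] = None,
    bins: str = "equal_count",
    sided: str = "two",
    alpha_gate: float = 0.05,
) -> AssociationResult:
    """Gradient-model fit with spin p-values for the gradient terms.

    The model t is recomputed under every permuted gradient.  The gradient
    main effect is always spin-tested; the gradient-by-hemisphere
    interaction only when its parametric p < `alpha_gate` (the screening
    rule: spin inference is reserved for terms that pass the parametric
    screen).
    """
    if spins.n_parcels != atlas.n_parcels:
        raise ValueError("spin set was generated on a different atlas")
    res = fit_gradient_model(em, atlas, family=family, gradient=gradient, bins=bins)
    res.sided = sided
    y, _, hemi, g_all, inc = _included_arrays(em, atlas, gradient)
    main = "gradient" if family in ("linear", "quadratic") else "step2"
    terms = [main]
    inter = f"{main}:hemisphere"
    if res.p_param.get(inter, 1.0) < alpha_gate:
        terms.append(inter)
    null = {term: np.empty(spins.n_perm) for term in terms}
    for k in range(spins.n_perm):
        g_perm = g_all[spins.perms[k]][inc]
        tvals = _term_t(y, g_perm, hemi, family, bins, terms)
        for term in terms:
            null[term][k] = tvals[term]
    for term in terms:
        obs = res.t[term]
        if not np.isfinite(obs):
            # degenerate (zero-residual) fit: maximal evidence, report the floor
            res.p_spin[term] = spin_pvalue(np.inf, null[term], sided="one")
            continue
        res.p_spin[term] = spin_pvalue(obs, null[term], sided=sided)
    return res


# ---------------------------------------------------------------------------
# step-versus-linear model comparison


def gaussian_aic_bic(rss: float, n: int, n_coef: int) -> tuple[float, float]:
    """AIC/BIC under the Gaussian maximum-likelihood convention.

    -2 log L = n log(RSS/n) up to a constant shared by all families, so the
    constant cancels in every comparison; the variance counts as one
    parameter.
    """
    k = n_coef + 1
    base = n * np.log(max(rss, 1e-300) / n)
    return base + 2 * k, base + k * np.log(n)


def verdict_from_deltas(d_aic: float, d_bic: float, threshold: float = 4.0) -> str:
    """Decision rule on (step - linear) information-criterion differences.

    linear_favoured iff both deltas exceed +threshold; step_favoured iff
    both fall below -threshold; otherwise indeterminate.
    """
    if d_aic > threshold and d_bic > threshold:
        return "linear_favoured"
    if d_aic < -threshold and d_bic < -threshold:
        return "step_favoured"
    return "indeterminate"


@dataclass
class ModelComparison:
    """Step-versus-linear comparison for one effect map."""

    parameter: str
    modality: str
    window: Optional[str]
    k: int
    d_aic: float
    d_bic: float
    verdict: str
    aic_linear: float
    aic_step: float
    bic_linear: float
    bic_step: float
    step_contrasts: List[dict] = field(default_factory=list)
    tag: str = "primary"

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "modality": self.modality,
            "window": self.window,
            "k": self.k,
            "d_aic": self.d_aic,
            "d_bic": self.d_bic,
            "verdict": self.verdict,
            "step_contrasts": self.step_contrasts,
            "tag": self.tag,
        }


def _step_contrast_stats(
    y: np.ndarray, g: np.ndarray, hemi: np.ndarray, k: int, bins: str
) -> Dict[tuple, float]:
    """t statistics of all pairwise step-level contrasts (bin means)."""
    x, names, _ = _family_design(g, hemi, f"step{k}", bins)
    beta, _, _, dof, rss, _ = _ols(x, y)
    xtx_inv = np.linalg.pinv(x.T @ x)
    sigma2 = rss / dof if dof > 0 else np.nan
    out = {}
    for a, b in itertools.combinations(range(k), 2):
        c = np.zeros(len(names))
        if a > 0:
            c[names.index(f"step{a + 1}")] -= 1.0
        if b > 0:
            c[names.index(f"step{b + 1}")] += 1.0
        var = float(c @ xtx_inv @ c) * sigma2
        out[(a + 1, b + 1)] = float(c @ beta) / np.sqrt(var) if var > 0 else np.nan
    return out


def compare_step_linear(
    em: EffectMap,
    atlas: ParcelAtlas,
    k: int = 3,
    spins: Optional[SpinSet] = None,
    gradient: Optional[np.ndarray] = None,
    bins: str = "equal_count",
    min_per_bin: int = 5,
    sided: str = "two",
) -> ModelComparison:
    """AIC/BIC comparison of the k-step model against the linear model.

    Both families are fit by least squares on the same parcels and scored
    under the same Gaussian likelihood; the verdict applies the +/-4 rule
    to (step - linear) differences.  When the linear model is not clearly
    favoured, pairwise step contrasts are computed, with spin p-values if a
    SpinSet is supplied.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    y, g, hemi, g_all, inc = _included_arrays(em, atlas, gradient)
    x_step, _, meta = _family_design(g, hemi, f"step{k}", bins)
    assign = meta["bins"]
    for h in (-0.5, 0.5):
        for b in range(k):
            if ((hemi == h) & (assign == b)).sum() < min_per_bin:
                raise ValueError(
                    f"step bin {b} has fewer than {min_per_bin} parcels in one hemisphere"
                )
    x_lin, _, _ = _family_design(g, hemi, "linear", bins)
    *_, rss_lin, _ = _ols(x_lin, y)
    *_, rss_step, _ = _ols(x_step, y)
    n = len(y)
    aic_l, bic_l = gaussian_aic_bic(rss_lin, n, x_lin.shape[1])
    aic_s, bic_s = gaussian_aic_bic(rss_step, n, x_step.shape[1])
    d_aic, d_bic = aic_s - aic_l, bic_s - bic_l
    verdict = verdict_from_deltas(d_aic, d_bic)
    comp = ModelComparison(
        parameter=em.parameter,
        modality=em.modality,
        window=em.window,
        k=k,
        d_aic=d_aic,
        d_bic=d_bic,
        verdict=verdict,
        aic_linear=aic_l,
        aic_step=aic_s,
        bic_linear=bic_l,
        bic_step=bic_s,
        tag=em.tag,
    )
    if verdict != "linear_favoured":
        obs = _step_contrast_stats(y, g, hemi, k, bins)
        null: Dict[tuple, np.ndarray] = {}
        if spins is not None:
            null = {pair: np.empty(spins.n_perm) for pair in obs}
            for j in range(spins.n_perm):
                perm_stats = _step_contrast_stats(y, g_all[spins.perms[j]][inc], hemi, k, bins)
                for pair in obs:
                    null[pair][j] = perm_stats[pair]
        for pair, tval in obs.items():
            entry = {"pair": f"step{pair[0]}_vs_step{pair[1]}", "t": tval}
            if spins is not None and np.isfinite(tval):
                entry["p_spin"] = spin_pvalue(tval, null[pair], sided=sided)
            comp.step_contrasts.append(entry)
    return comp


# ---------------------------------------------------------------------------
# duration-control combination rule


def combine_control(
    primary: AssociationResult,
    control: Optional[AssociationResult],
    alpha: float = 0.05,
    term: str = "gradient",
) -> dict:
    """Both-versions significance rule for the duration control.

    A parameter's gradient association counts as significant only when its
    spin p-value is below alpha in both the primary model (with word
    length) and the control model (with presentation duration).  Word
    length itself has no control counterpart and passes on the primary
    model alone.
    """
    p_primary = primary.p_spin.get(term)
    if p_primary is None:
        raise ValueError(f"primary result has no spin p-value for term {term!r}")
    if primary.parameter == "length":
        return {
            "parameter": primary.parameter,
            "term": term,
            "significant": bool(p_primary < alpha),
            "p_spin_primary": p_primary,
            "p_spin_control": None,
        }
    if control is None:
        raise ValueError(f"parameter {primary.parameter!r} requires a control result")
    if (
        control.parameter != primary.parameter
        or control.window != primary.window
        or control.family != primary.family
    ):
        raise ValueError("primary/control metadata mismatch")
    p_control = control.p_spin.get(term)
    if p_control is None:
        raise ValueError(f"control result has no spin p-value for term {term!r}")
    return {
        "parameter": primary.parameter,
        "term": term,
        "significant": bool(p_primary < alpha and p_control < alpha),
        "p_spin_primary": p_primary,
        "p_spin_control": p_control,
    }
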