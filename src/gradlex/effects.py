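"""Per-parcel effect maps of the psycholinguistic parameters.

Two routes produce `EffectMap`s:

* BOLD-style: an event-related design matrix (parametric word EVs with 1-s or
  actual durations, part-of-speech and sentence-level EVs, canonical
  double-gamma HRF convolution, temporal derivatives, discrete-cosine
  high-pass drift at 100 s), ordinary-least-squares first-level fits per
  parcel, and a group-level one-sample t converted to a signed two-tailed z
  (capped at |8|).

* MEG-style: a mass-univariate linear mixed model per parcel with a
  participant random intercept (REML), whose fixed-effect estimate per
  parameter forms the map; parcels with a boundary (zero) subject variance
  are refit by ordinary least squares and flagged.

The duration-control refit swaps presentation duration for word length,
producing a parallel map set used by the both-versions significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PARAMETERS
from .synth import TrialActivationTable

__all__ = [
    "EffectMap",
    "DesignMatrix",
    "FirstLevelResult",
    "double_gamma_hrf",
    "build_design_matrix",
    "fit_first_level",
    "group_z",
    "aggregate_vertices_to_parcels",
    "fit_mass_lmm",
    "duration_control_refit",
    "Z_CAP",
]

Z_CAP = 8.0


@dataclass
class EffectMap:
    """Per-parcel effect sizes of one parameter (group z or LMM estimate)."""

    parameter: str
    modality: str  # 'fmri_z' | 'meg_lmm'
    values: np.ndarray
    included: np.ndarray
    window: Optional[str] = None
    se: Optional[np.ndarray] = None
    sign_inverted: bool = False
    tag: str = "primary"  # 'primary' | 'control'
    flags: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.included = np.asarray(self.included, bool)
        if self.values.shape != self.included.shape:
            raise ValueError("values and included must have equal length")
        if not np.isfinite(self.values[self.included]).all():
            raise ValueError("non-finite values among included parcels")

    def copy(self) -> "EffectMap":
        return replace(self, values=self.values.copy(), included=self.included.copy())


# ---------------------------------------------------------------------------
# design matrix


def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1."""
    t = np.asarray(t, float)
    h = stats.gamma.pdf(t, peak) - stats.gamma.pdf(t, undershoot) / ratio
    m = h.max()
    return h / m if m > 0 else h


@dataclass
class DesignMatrix:
    """Sampled design: one column per EV (+ derivative), plus drift columns."""

    frame: pd.DataFrame  # index: scan time in seconds
    tr: float
    task_columns: list
    param_columns: Dict[str, str]

    @property
    def n_scans(self) -> int:
        return len(self.frame)


def _boxcar_convolved(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    dt: float,
    hrf: np.ndarray,
) -> np.ndarray:
    """Convolve amplitude-weighted boxcars with the HRF on a fine grid,
    then sample at scan onsets."""
    n_fine = int(np.ceil(n_scans * tr / dt)) + len(hrf)
    stick = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + dur) / dt)))
        stick[i0:min(i1, n_fine)] += amp
    conv = np.convolve(stick, hrf)[:n_fine] * dt
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


def _dct_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods >= cutoff seconds."""
    t_total = n_scans * tr
    order = int(np.floor(2.0 * t_total / cutoff))
    n = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design_matrix(
    events: pd.DataFrame,
    features: pd.DataFrame,
    tr: float,
    n_scans: Optional[int] = None,
    ev_scheme: str = "fixed_1s",
    length_variable: str = "length",
    hp_cutoff: float = 100.0,
    derivatives: bool = True,
    hrf_length: float = 32.0,
    dt: float = 0.1,
    check_rank: bool = True,
) -> DesignMatrix:
    """Event-related design: parametric word EVs, POS EVs, sentence EVs, drift.

    Word-parameter EVs carry the centred/scaled parameter value of included
    events with `fixed_1s` (1-s) or `actual_duration` boxcars; categorical
    part-of-speech EVs cover all word events; sentence-level EVs span each
    sentence; a fixation/cue EV covers the second before each sentence.
    Every task EV is convolved with the canonical HRF and paired with its
    temporal derivative; the 100-s high-pass is a discrete-cosine drift
    basis appended as nuisance columns.
    """
    if ev_scheme not in ("fixed_1s", "actual_duration"):
        raise ValueError(f"unknown ev_scheme {ev_scheme!r}")
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if len(events) and not events["onset"].is_monotonic_increasing:
        raise ValueError("events must be sorted by onset")
    if n_scans is None:
        t_end = (
            (events["onset"] + events["duration"]).max() + hrf_length
            if len(events)
            else hrf_length
        )
        n_scans = int(np.ceil(t_end / tr))
    hrf = double_gamma_hrf(np.arange(0.0, hrf_length, dt))

    params = [length_variable if p == "length" else p for p in PARAMETERS]
    cols: Dict[str, np.ndarray] = {}
    param_columns: Dict[str, str] = {}

    def add_ev(name: str, onsets, durations, amplitudes) -> None:
        cols[name] = _boxcar_convolved(
            np.asarray(onsets, float),
            np.asarray(durations, float),
            np.asarray(amplitudes, float),
            n_scans,
            tr,
            dt,
            hrf,
        )

    inc = features["included"].to_numpy(bool) if len(features) else np.array([], bool)
    if len(events):
        ev_dur = (
            np.ones(len(events)) if ev_scheme == "fixed_1s" else events["duration"].to_numpy(float)
        )
        for p in params:
            amps = np.zeros(len(events))
            if inc.any():
                amps[inc] = features.loc[features["included"], f"z_{p}"].to_numpy(float)
            add_ev(f"ev_{p}", events["onset"], ev_dur, amps)
            param_columns[p] = f"ev_{p}"
        for tag in ("noun", "adjective", "verb", "other"):
            mask = (events["pos_tag"] == tag).to_numpy()
            add_ev(
                f"pos_{tag}",
                events.loc[mask, "onset"],
                ev_dur[mask],
                np.ones(mask.sum()),
            )
        sent = events.drop_duplicates("sentence_id")
        for label, mask in (
            ("sentence_complex", sent["is_complex"] == 1),
            ("sentence_simple", sent["is_complex"] == 0),
        ):
            add_ev(
                label,
                sent.loc[mask, "sentence_onset"],
                sent.loc[mask, "sentence_duration"],
                np.ones(int(mask.sum())),
            )
        order = sent["order"].to_numpy(float)
        sd_order = order.std(ddof=1) if len(order) > 1 else 0.0
        z_order = (order - order.mean()) / sd_order if sd_order > 0 else order * 0.0
        add_ev("order", sent["sentence_onset"], sent["sentence_duration"], z_order)
        add_ev(
            "fixation",
            sent["sentence_onset"].to_numpy(float) - 1.0,
            np.ones(len(sent)),
            np.ones(len(sent)),
        )
    else:
        for p in params:
            cols[f"ev_{p}"] = np.zeros(n_scans)
            param_columns[p] = f"ev_{p}"

    task_columns = list(cols)
    if derivatives:
        scan_times = np.arange(n_scans) * tr
        for name in task_columns:
            cols[f"d_{name}"] = (
                np.gradient(cols[name], scan_times) if n_scans > 1 else np.zeros(n_scans)
            )
        task_columns = list(cols)

    drift = _dct_basis(n_scans, tr, hp_cutoff)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    cols["constant"] = np.ones(n_scans)

    frame = pd.DataFrame(cols, index=np.arange(n_scans) * tr)
    if check_rank:
        active = [c for c in frame.columns if np.linalg.norm(frame[c]) > 0]
        mat = frame[active].to_numpy(float)
        rank = np.linalg.matrix_rank(mat)
        if rank < len(active):
            # QR with pivoting: dependent columns are the ones pivoted last
            from scipy.linalg import qr

            _, r, piv = qr(mat, mode="economic", pivoting=True)
            dep = [active[j] for j in piv[rank:]]
            raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")
    return DesignMatrix(frame=frame, tr=tr, task_columns=task_columns, param_columns=param_columns)


# ---------------------------------------------------------------------------
# first level and group level


@dataclass
class FirstLevelResult:
    """Per-parcel OLS coefficients and standard errors for each design column."""

    coef: pd.DataFrame  # columns = design columns, rows = parcels
    se: pd.DataFrame
    dof: int


def fit_first_level(series: np.ndarray, design: DesignMatrix) -> FirstLevelResult:
    """Ordinary least squares per parcel: series (n_scans, n_parcels)."""
    y = np.asarray(series, float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.frame.to_numpy(float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("series length does not match design")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite values")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rank = np.linalg.matrix_rank(x)
    dof = y.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    xtx_inv_diag = np.diag(np.linalg.pinv(x.T @ x))
    se = np.sqrt(np.maximum(0.0, xtx_inv_diag[:, None] * sigma2[None, :]))
    names = list(design.frame.columns)
    return FirstLevelResult(
        coef=pd.DataFrame(beta.T, columns=names),
        se=pd.DataFrame(se.T, columns=names),
        dof=dof,
    )


def group_z(
    coefs: np.ndarray,
    parameter: str,
    included: Optional[np.ndarray] = None,
    window: Optional[str] = None,
    tag: str = "primary",
) -> EffectMap:
    """Group-level signed two-tailed z from per-subject first-level coefficients.

    One-sample t across subjects per parcel (summary-statistics approach),
    converted to a two-tailed p and then to a z carrying the sign of the
    cross-subject mean, capped at |8| to stay finite under degenerate
    between-subject variance.
    """
    c = np.asarray(coefs, float)
    if c.ndim != 2 or c.shape[0] < 3:
        raise ValueError("need coefficients from at least 3 subjects")
    n = c.shape[0]
    mean = c.mean(axis=0)
    sd = c.std(axis=0, ddof=1)
    z = np.empty(c.shape[1])
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn("zero between-subject variance; z capped", RuntimeWarning)
        z[zero_var] = np.sign(mean[zero_var]) * Z_CAP
    ok = ~zero_var
    t = mean[ok] / (sd[ok] / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zval = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    z[ok] = np.sign(mean[ok]) * np.minimum(zval, Z_CAP)
    z[ok & (mean == 0)] = 0.0
    if included is None:
        included = np.ones(c.shape[1], bool)
    return EffectMap(
        parameter=parameter,
        modality="fmri_z",
        values=z,
        included=included,
        window=window,
        tag=tag,
    )


def aggregate_vertices_to_parcels(
    vertex_values: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    n_parcels: Optional[int] = None,
    weight_threshold: float = 0.75,
    coverage_threshold: float = 0.25,
):
    """Average vertex values into parcels with coverage-based inclusion.

    Vertices whose field-of-view mask weight fell below `weight_threshold`
    after interpolation are dropped; a parcel is included iff at least
    `coverage_threshold` of its vertices survive.  Returns
    (parcel_values, included).
    """
    v = np.asarray(vertex_values, float)
    lab = np.asarray(labels, int)
    w = np.asarray(weights, float)
    if not (len(v) == len(lab) == len(w)):
        raise ValueError("vertex arrays must have equal length")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("weights must lie in [0, 1]")
    if n_parcels is None:
        n_parcels = int(lab.max()) + 1
    values = np.full(n_parcels, np.nan)
    included = np.zeros(n_parcels, bool)
    keep = w >= weight_threshold
    for p in range(n_parcels):
        in_parcel = lab == p
        total = int(in_parcel.sum())
        if total == 0:
            continue
        surv = in_parcel & keep
        if surv.sum() / total >= coverage_threshold and surv.any():
            values[p] = v[surv].mean()
            included[p] = True
    return values, included


# ---------------------------------------------------------------------------
# MEG-style mass-univariate linear mixed models


def _lmm_design(
    features: pd.DataFrame, trials: np.ndarray, length_variable: str
) -> tuple[np.ndarray, list]:
    """Fixed-effects design shared by every parcel's LMM."""
    rows = features.loc[trials]
    params = [length_variable if p == "length" else p for p in PARAMETERS]
    names = [f"z_{p}" for p in params]
    mats = [rows[n].to_numpy(float) for n in names]
    # POS among content words is noun/adjective/verb; treatment coding, 'noun' reference
    for tag in ("adjective", "verb"):
        mats.append((rows["pos_tag"] == tag).to_numpy(float))
        names.append(f"pos_{tag}")
    mats.append(rows["complexity"].to_numpy(float))
    names.append("complexity")
    mats.append(rows["z_order"].to_numpy(float))
    names.append("z_order")
    mats.append(np.ones(len(rows)))
    names.append("const")
    x = np.column_stack(mats)
    for j, name in enumerate(names[:-1]):
        if np.std(x[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant in the fitted population")
    return x, names


def fit_mass_lmm(
    trials: TrialActivationTable,
    features: pd.DataFrame,
    length_variable: str = "length",
    reml: bool = True,
    tag: str = "primary",
    force_zero_subject_variance: bool = False,
) -> Dict[str, EffectMap]:
    """Per-parcel linear mixed model with a participant random intercept.

    activation ~ length + old20 + logfreq + semsim + position + pos_tag
                 + complexity + order + (1 | subject), fit by REML.
    If the subject variance component converges to the boundary (zero), the
    parcel is refit by ordinary least squares and flagged `ols_fallback`;
    `force_zero_subject_variance` pins the component at zero up front, which
    reduces every parcel to exactly the ordinary-least-squares fit.
    Returns one EffectMap (estimate + standard error) per parameter.
    """
    import statsmodels.api as sm

    if len(trials.subjects) < 2:
        raise ValueError("need at least 2 subjects")
    x, names = _lmm_design(features, trials.trials, length_variable)
    n_subj, n_trial, n_parcel = trials.activation.shape
    x_full = np.tile(x, (n_subj, 1))
    groups = np.repeat(trials.subjects, n_trial)
    params = [length_variable if p == "length" else p for p in PARAMETERS]
    est = {p: np.empty(n_parcel) for p in params}
    se = {p: np.empty(n_parcel) for p in params}
    fallback = np.zeros(n_parcel, bool)
    col = {p: names.index(f"z_{p}") for p in params}
    for j in range(n_parcel):
        y = trials.activation[:, :, j].reshape(-1)
        if force_zero_subject_variance:
            res, singular = None, True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x_full, groups=groups)
                try:
                    res = model.fit(reml=reml)
                    singular = float(np.asarray(res.cov_re)[0, 0]) <= 1e-8 * max(y.var(), 1e-12)
                except Exception:
                    res, singular = None, True
        if singular or res is None:
            ols = sm.OLS(y, x_full).fit()
            fallback[j] = True
            fe, bse = ols.params, ols.bse
        else:
            fe, bse = res.fe_params, res.bse_fe
        for p in params:
            est[p][j] = fe[col[p]]
            se[p][j] = bse[col[p]]
    included = np.ones(n_parcel, bool)
    return {
        p: EffectMap(
            parameter=p,
            modality="meg_lmm",
            values=est[p],
            se=se[p],
            included=included,
            window=trials.window,
            tag=tag,
            flags={"ols_fallback": fallback.copy()},
        )
        for p in params
    }


def duration_control_refit(
    trials: TrialActivationTable,
    features: pd.DataFrame,
    reml: bool = True,
) -> Dict[str, EffectMap]:
    """Refit the mass LMMs with presentation duration in place of word length.

    Emits a parallel map set tagged `control`; the word-length slot is
    occupied by the duration parameter.
    """
    if "z_duration" not in features.columns:
        raise ValueError("features lack a standardized duration column")
    return fit_mass_lmm(
        trials, features, length_variable="duration", reml=reml, tag="control"
    )
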