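"""Synthetic reading-study generator.

Generates every input the analysis pipeline consumes, with the statistical
structure the downstream models assume: a Zipf-distributed lexicon, topic-
structured word embeddings, 9-15-word sentences with content and function
words, a bi-hemispheric spherical parcel atlas carrying a smooth
unimodal-to-heteromodal gradient, and parcel responses whose sensitivity to
each psycholinguistic parameter varies linearly or stepwise along the
gradient, on top of spatially autocorrelated map noise, participant random
intercepts and trial noise (MEG-style trials) or AR(1) noise (BOLD-style
series).

All generators are pure functions of (inputs, seed): identical seeds give
identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._rng import substream
from .atlas import ParcelAtlas
from .config import PARAMETERS, SimConfig, TrueProfile

__all__ = [
    "Lexicon",
    "EmbeddingTable",
    "TrialActivationTable",
    "SyntheticStudy",
    "simulate_lexicon",
    "simulate_embeddings",
    "simulate_sentences",
    "simulate_atlas",
    "simulate_effect_profile",
    "simulate_meg_trials",
    "simulate_bold_study",
    "gaussian_field",
    "make_study",
]

_ALPHABET = string.ascii_lowercase


# ---------------------------------------------------------------------------
# containers


@dataclass
class Lexicon:
    """Word-frequency lexicon: unique words with corpus token counts."""

    table: pd.DataFrame  # columns: word, count

    def __post_init__(self) -> None:
        if self.table["word"].duplicated().any():
            raise ValueError("lexicon words must be unique")
        if (self.table["count"] < 0).any():
            raise ValueError("lexicon counts must be >= 0")
        if self.total_tokens <= 0:
            raise ValueError("lexicon total token count must be > 0")

    @property
    def words(self) -> np.ndarray:
        return self.table["word"].to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    @property
    def total_tokens(self) -> int:
        return int(self.table["count"].sum())

    @property
    def per_million(self) -> np.ndarray:
        return self.counts / self.total_tokens * 1e6

    def count_of(self, word: str) -> Optional[int]:
        if not hasattr(self, "_index"):
            self._index = {w.casefold(): int(c) for w, c in zip(self.words, self.counts)}
        return self._index.get(word.casefold())


@dataclass
class EmbeddingTable:
    """(word, occurrence_id) -> d-dimensional vector, plus topic labels.

    Synthetic vectors are type-level, so every token uses occurrence_id 0;
    the key structure still supports contextualised (per-occurrence) vectors
    supplied from outside.
    """

    table: pd.DataFrame  # columns: word, occurrence_id, topic, v0..v{d-1}

    def __post_init__(self) -> None:
        self.vector_columns = [c for c in self.table.columns if c.startswith("v")]
        if not self.vector_columns:
            raise ValueError("embedding table has no vector columns")
        mat = self.table[self.vector_columns].to_numpy(float)
        if not np.isfinite(mat).all():
            raise ValueError("embedding vectors contain non-finite components")
        self._matrix = mat
        self._index = {
            (w, int(o)): i
            for i, (w, o) in enumerate(zip(self.table["word"], self.table["occurrence_id"]))
        }

    @property
    def dim(self) -> int:
        return len(self.vector_columns)

    def vector(self, word: str, occurrence_id: int = 0) -> np.ndarray:
        key = (word, int(occurrence_id))
        if key not in self._index:
            raise KeyError(f"no embedding for word {word!r} (occurrence {occurrence_id})")
        return self._matrix[self._index[key]]

    def has(self, word: str, occurrence_id: int = 0) -> bool:
        return (word, int(occurrence_id)) in self._index

    def topic_of(self, word: str) -> int:
        key = (word, 0)
        return int(self.table["topic"].iloc[self._index[key]])


@dataclass
class TrialActivationTable:
    """MEG-style per-trial parcel activations for one 100-ms window.

    activation has shape (n_subjects, n_trials, n_parcels); `trials` holds
    the row labels of the corresponding events in the feature table.
    """

    activation: np.ndarray
    subjects: np.ndarray
    trials: np.ndarray
    parcel_ids: np.ndarray
    window: str

    def __post_init__(self) -> None:
        if self.activation.shape != (len(self.subjects), len(self.trials), len(self.parcel_ids)):
            raise ValueError("activation shape inconsistent with labels")
        if not np.isfinite(self.activation).all():
            raise ValueError("activations must be finite")

    def to_frame(self) -> pd.DataFrame:
        s, t, p = self.activation.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.trials, self.parcel_ids],
            names=["subject", "trial", "parcel_id"],
        )
        df = pd.DataFrame({"activation": self.activation.ravel()}, index=idx).reset_index()
        df["window"] = self.window
        return df[["subject", "trial", "parcel_id", "window", "activation"]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialActivationTable":
        windows = df["window"].unique()
        if len(windows) != 1:
            raise ValueError("expected a single window per table")
        subjects = np.sort(df["subject"].unique())
        trials = np.sort(df["trial"].unique())
        parcels = np.sort(df["parcel_id"].unique())
        pivot = df.set_index(["subject", "trial", "parcel_id"])["activation"]
        full = pd.MultiIndex.from_product([subjects, trials, parcels])
        if len(pivot) != len(full):
            raise ValueError("trial table is not a full subject x trial x parcel grid")
        act = pivot.reindex(full).to_numpy().reshape(len(subjects), len(trials), len(parcels))
        return cls(act, subjects, trials, parcels, str(windows[0]))


# ---------------------------------------------------------------------------
# lexicon and embeddings


def simulate_lexicon(config: SimConfig) -> Lexicon:
    """Unique letter strings with Zipf rank-frequency counts.

    Lengths are uniform on `length_range`; the count of the word at rank r
    is proportional to r**-zipf_exponent, so a log-log regression of count
    on rank recovers the exponent.

    Words are drawn as orthographic families — a base string plus a
    heavy-tailed number of one-to-two-edit variants — so neighbourhood
    density varies widely at a given length, as in natural lexicons.
    Uniform random strings would instead make the 20-nearest-neighbour
    distance an almost deterministic function of word length, collapsing
    the length and orthographic-familiarity predictors into one.
    """
    config.validate()
    rng = substream(config.seed, "lexicon")
    lo, hi = config.length_range
    capacity = sum(26**ell for ell in range(lo, hi + 1))
    if capacity < config.n_words:
        raise ValueError(
            f"alphabet too small: {capacity} distinct strings of length {lo}-{hi}"
            f" < n_words={config.n_words}"
        )
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < config.n_words:
        ell = int(rng.integers(lo, hi + 1))
        base = "".join(_ALPHABET[i] for i in rng.integers(0, 26, size=ell))
        u = rng.random()
        if u < 0.35:
            n_family = 1 + int(rng.poisson(22))  # dense neighbourhood
        elif u < 0.65:
            n_family = 1 + int(rng.poisson(5))  # moderate neighbourhood
        else:
            n_family = 1  # hermit word
        family = [base]
        for _ in range(n_family - 1):
            w = list(base)
            for _edit in range(1 + (rng.random() < 0.3)):
                w[int(rng.integers(0, ell))] = _ALPHABET[int(rng.integers(0, 26))]
            family.append("".join(w))
        for w in family:
            if w not in seen and len(words) < config.n_words:
                seen.add(w)
                words.append(w)
    ranks = np.arange(1, config.n_words + 1, dtype=float)
    counts = np.maximum(1, np.round(1e7 * ranks**-config.zipf_exponent)).astype(np.int64)
    return Lexicon(pd.DataFrame({"word": words, "count": counts}))


def simulate_embeddings(lexicon: Lexicon, config: SimConfig) -> EmbeddingTable:
    """Unit-norm topic-structured vectors.

    Each word is assigned a topic; its vector is the unit-normalised mix
    coherence * topic_centroid + (1 - coherence) * noise, so same-topic
    pairs have higher expected cosine than cross-topic pairs, and
    coherence=1 collapses each topic onto a single direction.
    """
    config.validate()
    if config.embed_dim < 2:
        raise ValueError("embed_dim must be >= 2")
    if config.n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    rng = substream(config.seed, "embeddings")
    d, k = config.embed_dim, config.n_topics
    centroids = rng.standard_normal((k, d))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    n = len(lexicon.words)
    topics = rng.integers(0, k, size=n)
    noise = rng.standard_normal((n, d))
    noise /= np.linalg.norm(noise, axis=1, keepdims=True)
    c = config.topic_coherence
    vecs = c * centroids[topics] + (1.0 - c) * noise
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    df = pd.DataFrame(vecs, columns=[f"v{i}" for i in range(d)])
    df.insert(0, "topic", topics)
    df.insert(0, "occurrence_id", 0)
    df.insert(0, "word", lexicon.words)
    return EmbeddingTable(df)


# ---------------------------------------------------------------------------
# sentences


def simulate_sentences(
    lexicon: Lexicon, embeddings: EmbeddingTable, config: SimConfig
) -> pd.DataFrame:
    """Word-presentation event table for one pass through the stimuli.

    Each sentence has a dominant topic; content words come from that topic
    with probability `topic_fidelity` (else from another topic), function
    words from the highest-frequency entries.  Presentation duration grows
    with word length (emulating length-yoked presentation), onsets increase
    monotonically, and each sentence is preceded by a 1-s fixation/cue
    period and followed by a 2-s blank.
    """
    config.validate()
    if len(lexicon.words) == 0:
        raise ValueError("lexicon is empty")
    rng = substream(config.seed, "sentences")
    topics = embeddings.table["topic"].to_numpy()
    words = embeddings.table["word"].to_numpy()
    by_topic = {t: words[topics == t] for t in np.unique(topics)}
    # function words: most frequent lexicon entries (Zipf head)
    head = lexicon.table.nlargest(min(30, len(words)), "count")["word"].to_numpy()
    content_pos_tags = np.array(["noun", "adjective", "verb"])

    rows = []
    t = 0.0
    lo, hi = config.sentence_length_range
    for s in range(config.n_sentences):
        length = int(rng.integers(lo, hi + 1))
        topic = int(rng.choice(list(by_topic)))
        is_complex = bool(rng.random() < 0.5)
        t += 1.0  # fixation + cue before the sentence
        sent_onset = t
        for pos in range(1, length + 1):
            is_content = pos > 1 and bool(rng.random() < config.content_prob)
            if is_content:
                if rng.random() < config.topic_fidelity or len(by_topic) == 1:
                    pool = by_topic[topic]
                else:
                    other = int(rng.choice([k for k in by_topic if k != topic]))
                    pool = by_topic[other]
                word = str(rng.choice(pool))
                pos_tag = str(rng.choice(content_pos_tags))
            else:
                word = str(rng.choice(head))
                pos_tag = "other"
            # length-yoked duration with jitter: corr(length, duration) ~ .9
            duration = float(np.clip(0.16 + 0.09 * len(word) + rng.normal(0.0, 0.10), 0.16, 1.4))
            rows.append(
                dict(
                    sentence_id=s,
                    order=s,
                    is_complex=int(is_complex),
                    topic=topic,
                    word=word,
                    position=pos,
                    pos_tag=pos_tag,
                    is_content=bool(is_content),
                    onset=round(t, 6),
                    duration=round(duration, 6),
                    occurrence_id=0,
                )
            )
            t += duration
        sent_dur = t - sent_onset
        for r in rows[-length:]:
            r["sentence_onset"] = round(sent_onset, 6)
            r["sentence_duration"] = round(sent_dur, 6)
        t += 2.0  # blank between sentences (implicit baseline)
    events = pd.DataFrame(rows)
    events.index.name = "event"
    return events


# ---------------------------------------------------------------------------
# atlas and spatial fields


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic even-coverage lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gaussian_field(
    xyz: np.ndarray, corr_length: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian field with exponential covariance over chordal distance.

    cov(i, j) = sd^2 * exp(-d_ij / corr_length); corr_length = 0 gives
    spatially white noise.
    """
    n = len(xyz)
    if sd == 0.0:
        return np.zeros(n)
    if corr_length <= 0.0:
        return sd * rng.standard_normal(n)
    d2 = np.maximum(
        0.0,
        (xyz**2).sum(1)[:, None] + (xyz**2).sum(1)[None, :] - 2.0 * xyz @ xyz.T,
    )
    cov = sd**2 * np.exp(-np.sqrt(d2) / corr_length)
    cov[np.diag_indices(n)] += 1e-10 * sd**2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def simulate_atlas(config: SimConfig) -> ParcelAtlas:
    """Mirror-symmetric spherical atlas with a smooth gradient map.

    Left-hemisphere centroids form a Fibonacci lattice on the unit sphere;
    right-hemisphere centroids are their x-mirror.  The gradient is the
    anterior-posterior (y) coordinate plus a smooth random field, min-max
    rescaled to `gradient_range` exactly.
    """
    config.validate()
    rng = substream(config.seed, "atlas")
    n = config.n_parcels_per_hemi
    left = _fibonacci_sphere(n)
    right = left.copy()
    right[:, 0] *= -1.0
    xyz = np.vstack([left, right])
    folded = xyz.copy()
    folded[n:, 0] *= -1.0
    raw = xyz[:, 1] + gaussian_field(folded, config.spatial_corr_length, 0.3, rng)
    g0, g1 = config.gradient_range
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    gradient = g0 + raw * (g1 - g0)
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(2 * n),
            "hemisphere": ["L"] * n + ["R"] * n,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "gradient": gradient,
        }
    )
    return ParcelAtlas(table)


def step_levels(gradient: np.ndarray, levels: Sequence[float]) -> np.ndarray:
    """Ground-truth step profile: equal-count gradient bins mapped to levels."""
    k = len(levels)
    qs = np.quantile(gradient, np.linspace(0, 1, k + 1)[1:-1])
    bins = np.digitize(gradient, qs)
    return np.asarray(levels, float)[bins]


def simulate_effect_profile(
    atlas: ParcelAtlas,
    profile: TrueProfile,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-parcel sensitivity map: shape(gradient) + spatially correlated noise.

    The noise is a zero-mean Gaussian field with exponential covariance over
    chordal distance between (folded) centroids, length scale
    `config.spatial_corr_length` and sd `profile.noise_sd`.
    """
    profile.validate()
    if rng is None:
        rng = substream(config.seed, f"profile:{profile.parameter}:{profile.shape}")
    g = atlas.gradient
    if profile.shape == "linear":
        base = profile.intercept + profile.slope * g
    elif profile.shape == "null":
        base = np.full_like(g, profile.intercept)
    else:
        base = step_levels(g, profile.levels)
    noise = gaussian_field(
        atlas.folded_centroids(), config.spatial_corr_length, profile.noise_sd, rng
    )
    return base + noise


# ---------------------------------------------------------------------------
# neural responses


def simulate_meg_trials(
    features: pd.DataFrame,
    sensitivities: Mapping[str, np.ndarray],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    window: str = "0-100",
) -> TrialActivationTable:
    """Per-trial parcel activations from a linear sensitivity model.

    activation(subject, trial, parcel) =
        sum_param sensitivity[param][parcel] * z_param[trial]
        + u_subject + e,   u ~ N(0, subj_sd^2), e ~ N(0, trial_sd^2).

    Only included trials (content words at position >= 6) are generated;
    with the default study conditions this is roughly 240 trials per
    participant.
    """
    config.validate()
    if rng is None:
        rng = substream(config.seed, f"meg:{window}")
    missing = [p for p in sensitivities if f"z_{p}" not in features.columns]
    if missing:
        raise ValueError(f"features lack standardized columns for parameters: {missing}")
    inc = features[features["included"]]
    x = np.column_stack([inc[f"z_{p}"].to_numpy(float) for p in sensitivities])
    if not np.isfinite(x).all():
        raise ValueError("non-finite standardized features among included trials")
    smaps = np.column_stack([np.asarray(sensitivities[p], float) for p in sensitivities])
    n_parcels = smaps.shape[0]
    signal = x @ smaps.T  # (n_trials, n_parcels)
    s, t = config.n_subjects, len(inc)
    u = rng.normal(0.0, config.subj_sd, size=s)
    e = rng.normal(0.0, config.trial_sd, size=(s, t, n_parcels))
    act = signal[None, :, :] + u[:, None, None] + e
    return TrialActivationTable(
        activation=act,
        subjects=np.arange(s),
        trials=inc.index.to_numpy(),
        parcel_ids=np.arange(n_parcels),
        window=window,
    )


def simulate_bold_study(
    events: pd.DataFrame,
    features: pd.DataFrame,
    sensitivities: Mapping[str, np.ndarray],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ev_scheme: str = "fixed_1s",
    nuisance_beta_sd: float = 0.0,
):
    """BOLD-style parcel time series for each subject.

    Builds the word/sentence design matrix once (all subjects see the same
    stimuli), sets each parameter EV's per-parcel beta from its sensitivity
    map, optionally draws small nuisance betas for the remaining task EVs,
    and adds AR(1) noise with coefficient `ar1_phi` and marginal sd
    `trial_sd`.  Returns (design, list of (n_scans, n_parcels) arrays).
    """
    from .effects import build_design_matrix  # deferred: avoid circular import

    config.validate()
    if rng is None:
        rng = substream(config.seed, "bold")
    design = build_design_matrix(events, features, tr=config.tr, ev_scheme=ev_scheme)
    x = design.frame.to_numpy(float)
    names = list(design.frame.columns)
    n_parcels = len(next(iter(sensitivities.values())))
    betas = np.zeros((len(names), n_parcels))
    for param, smap in sensitivities.items():
        col = design.param_columns.get(param)
        if col is None:
            raise ValueError(f"design has no EV for parameter {param!r}")
        betas[names.index(col)] = np.asarray(smap, float)
    if nuisance_beta_sd > 0:
        param_cols = set(design.param_columns.values())
        for j, name in enumerate(names):
            if name in design.task_columns and name not in param_cols:
                betas[j] = rng.normal(0.0, nuisance_beta_sd, size=n_parcels)
    mean = x @ betas
    phi, sd = config.ar1_phi, config.trial_sd
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    series = []
    for _ in range(config.n_subjects):
        w = rng.normal(0.0, innov_sd, size=mean.shape)
        noise = lfilter([1.0], [1.0, -phi], w, axis=0)
        series.append(mean + noise)
    return design, series


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic study, ready for the pipeline."""

    config: SimConfig
    lexicon: Lexicon
    embeddings: EmbeddingTable
    events: pd.DataFrame
    features: pd.DataFrame
    atlas: ParcelAtlas
    profiles: Dict[str, TrueProfile]
    sensitivities: Dict[str, np.ndarray]
    trials: Dict[str, TrialActivationTable] = field(default_factory=dict)


def make_study(
    config: SimConfig,
    profiles: Mapping[str, TrueProfile],
    windows: Sequence[str] = ("0-100",),
) -> SyntheticStudy:
    """Generate lexicon, sentences, features, atlas, profiles and MEG trials."""
    from .features import build_feature_table  # deferred: avoid circular import

    lexicon = simulate_lexicon(config)
    embeddings = simulate_embeddings(lexicon, config)
    events = simulate_sentences(lexicon, embeddings, config)
    features = build_feature_table(events, lexicon, embeddings)
    atlas = simulate_atlas(config)
    sens = {
        name: simulate_effect_profile(atlas, prof, config) for name, prof in profiles.items()
    }
    trials = {
        w: simulate_meg_trials(features, sens, config, window=w) for w in windows
    }
    return SyntheticStudy(
        config=config,
        lexicon=lexicon,
        embeddings=embeddings,
        events=events,
        features=features,
        atlas=atlas,
        profiles=dict(profiles),
        sensitivities=sens,
        trials=trials,
    )
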