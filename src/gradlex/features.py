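"""Word-level and contextual psycholinguistic predictors.

Computes the five parameters of interest for every word event — word length,
OLD20 (mean Levenshtein distance to the 20 nearest orthographic neighbours),
log10 frequency per million, semantic similarity (cosine between a word's
vector and the mean vector of the five preceding words), and sentence
position — plus control predictors (presentation duration, syntactic
complexity, presentation order), applies the inclusion rule (content words
from sentence position six onwards), and centres/scales all numeric
predictors over the included events.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

try:  # fast C edit distance for ASCII input
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from .synth import EmbeddingTable, Lexicon

__all__ = [
    "levenshtein",
    "compute_old20",
    "log_frequency_per_million",
    "phrase_vector",
    "semantic_similarity",
    "build_feature_table",
    "collinearity_check",
    "standardize",
    "NUMERIC_PREDICTORS",
]

#: numeric predictors that get a standardized z_ column
NUMERIC_PREDICTORS = ("length", "old20", "logfreq", "semsim", "position", "duration", "order")


def _levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (insert/delete/substitute)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein(a: str, b: str) -> int:
    """Minimum number of insertions/deletions/substitutions turning a into b."""
    if not a or not b:
        return len(a) + len(b)
    if _HAVE_EDLIB and a.isascii() and b.isascii():
        return int(edlib.align(a, b, task="distance")["editDistance"])
    return _levenshtein_dp(a, b)


def compute_old20(word: str, lexicon: Lexicon, n_neighbours: int = 20) -> float:
    """Mean Levenshtein distance from `word` to its 20 nearest lexicon neighbours.

    Entries identical to the word itself (case-folded comparison) are
    excluded, per the standard definition of orthographic neighbourhood
    distance; ties beyond rank 20 are broken at the value level, so the
    result does not depend on lexicon order.
    """
    w = word.casefold()
    dists = [
        levenshtein(w, other.casefold())
        for other in lexicon.words
        if other.casefold() != w
    ]
    if len(dists) < n_neighbours:
        raise ValueError(
            f"lexicon has only {len(dists)} eligible neighbours for {word!r}"
            f" (need {n_neighbours})"
        )
    arr = np.partition(np.asarray(dists, float), n_neighbours - 1)[:n_neighbours]
    return float(arr.mean())


def log_frequency_per_million(count: float, total_tokens: float, smooth: bool = True) -> float:
    """log10 frequency per million tokens, with add-one count smoothing.

    The smoothed form log10((count+1)/total * 1e6) is the Subtlex-style
    convention; `smooth=False` gives the raw transform and rejects zero
    counts.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if total_tokens <= 0:
        raise ValueError("total_tokens must be > 0")
    c = count + 1 if smooth else count
    if c <= 0:
        raise ValueError("zero count requires smoothing")
    return float(np.log10(c / total_tokens * 1e6))


def phrase_vector(context_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Component-wise mean of exactly five context-word vectors."""
    if len(context_vectors) != 5:
        raise ValueError(f"expected exactly 5 context vectors, got {len(context_vectors)}")
    arrs = [np.asarray(v, float) for v in context_vectors]
    dims = {a.shape for a in arrs}
    if len(dims) != 1 or arrs[0].ndim != 1:
        raise ValueError(f"context vectors have mixed shapes: {sorted(dims)}")
    return np.mean(arrs, axis=0)


def semantic_similarity(word_vector: np.ndarray, phrase: np.ndarray) -> float:
    """Cosine similarity between a word vector and a phrase vector."""
    u = np.asarray(word_vector, float)
    v = np.asarray(phrase, float)
    if u.shape != v.shape:
        raise ValueError("vectors have different dimensions")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def standardize(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Centre and scale to sd 1 (sample sd); idempotent on standardized input."""
    x = np.asarray(x, float)
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=ddof)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - mu) / sd


def build_feature_table(
    events: pd.DataFrame,
    lexicon: Lexicon,
    embeddings: EmbeddingTable,
    smooth_freq: bool = True,
) -> pd.DataFrame:
    """Per-event predictor table with inclusion flags and standardized columns.

    An event is `included` iff it is a content word at sentence position >= 6
    (the earliest position with a full five-word context).  Standardization
    (mean 0, sd 1) is computed over included events only — the modelling
    population — and raw values are preserved alongside.  Missing lexicon or
    embedding coverage for an included word is an error naming the word;
    for excluded words it yields NaN.
    """
    feats = events.copy()
    feats["length"] = feats["word"].str.len()
    feats["included"] = feats["is_content"].astype(bool) & (feats["position"] >= 6)
    feats["complexity"] = feats["is_complex"].astype(int)

    total = lexicon.total_tokens
    old20_cache: dict[str, float] = {}
    logfreq_cache: dict[str, Optional[float]] = {}

    def word_stats(word: str, required: bool):
        w = word.casefold()
        if w not in logfreq_cache:
            cnt = lexicon.count_of(w)
            logfreq_cache[w] = (
                None if cnt is None else log_frequency_per_million(cnt, total, smooth_freq)
            )
            old20_cache[w] = compute_old20(w, lexicon) if cnt is not None else np.nan
        if logfreq_cache[w] is None:
            if required:
                raise ValueError(f"no lexicon entry for included word {word!r}")
            return np.nan, np.nan
        return old20_cache[w], logfreq_cache[w]

    old20s, logfreqs, semsims = [], [], []
    by_sentence = {
        sid: grp.sort_values("position") for sid, grp in events.groupby("sentence_id")
    }
    for idx, row in feats.iterrows():
        required = bool(row["included"])
        o, f = word_stats(row["word"], required)
        old20s.append(o)
        logfreqs.append(f)
        sim = np.nan
        if row["position"] >= 6:
            sent = by_sentence[row["sentence_id"]]
            ctx = sent[sent["position"].between(row["position"] - 5, row["position"] - 1)]
            have = all(
                embeddings.has(w, occ) for w, occ in zip(ctx["word"], ctx["occurrence_id"])
            ) and embeddings.has(row["word"], row["occurrence_id"])
            if not have:
                missing = [
                    w
                    for w, occ in zip(
                        list(ctx["word"]) + [row["word"]],
                        list(ctx["occurrence_id"]) + [row["occurrence_id"]],
                    )
                    if not embeddings.has(w, occ)
                ]
                if required:
                    raise ValueError(f"no embedding for word {missing[0]!r}")
            else:
                phrase = phrase_vector(
                    [embeddings.vector(w, occ) for w, occ in zip(ctx["word"], ctx["occurrence_id"])]
                )
                sim = semantic_similarity(
                    embeddings.vector(row["word"], row["occurrence_id"]), phrase
                )
        semsims.append(sim)
    feats["old20"] = old20s
    feats["logfreq"] = logfreqs
    feats["semsim"] = semsims

    inc = feats["included"].to_numpy()
    for col in NUMERIC_PREDICTORS:
        vals = feats[col].to_numpy(float)
        if not np.isfinite(vals[inc]).all():
            raise ValueError(f"non-finite {col} among included events")
        mu = vals[inc].mean()
        sd = vals[inc].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant over included events")
        feats[f"z_{col}"] = (vals - mu) / sd
    return feats


def collinearity_check(x: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing column j on all other columns plus an
    intercept.  Exactly collinear columns are reported with infinite VIF and
    a failure flag.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least two columns")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more rows than columns")
    mat = x.to_numpy(float)
    out = []
    for j in range(mat.shape[1]):
        y = mat[:, j]
        others = np.column_stack(
            [np.ones(len(y)), np.delete(mat, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 0.0 if tss == 0 else 1.0 - (resid**2).sum() / tss
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"column": x.columns[j], "vif": vif, "flagged": bool(vif >= threshold)})
    return pd.DataFrame(out)
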