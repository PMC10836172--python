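"""Configuration objects for the synthetic reading study.

`SimConfig` collects the knobs of the synthetic-data generator: the lexicon,
the sentence material, the topic-structured embedding space, the spherical
bi-hemispheric parcel atlas, and the neural response model (participant
intercepts, trial noise, AR(1) BOLD noise).  `TrueProfile` describes the
ground-truth dependence of one parameter's parcel sensitivity on the gradient
(linear, 2/3-step, or null), which the recovery and model-selection analyses
try to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

__all__ = ["SimConfig", "TrueProfile", "PARAMETERS"]

#: The five word/contextual parameters of interest, in canonical order.
PARAMETERS = ("length", "old20", "logfreq", "semsim", "position")


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    Defaults emulate the sentence-reading study the pipeline is designed for:
    9–15-word sentences, ~240 analysed content words per participant, a
    bi-hemispheric parcel atlas with a smooth unimodal-to-heteromodal
    gradient, and word presentation durations tied to word length.
    """

    # lexicon
    n_words: int = 2000
    length_range: Tuple[int, int] = (3, 10)
    zipf_exponent: float = 1.0

    # sentence material
    n_sentences: int = 60
    sentence_length_range: Tuple[int, int] = (9, 15)
    content_prob: float = 0.65  # chance a non-initial slot holds a content word
    topic_fidelity: float = 0.8  # chance a content word comes from the sentence topic

    # embeddings
    embed_dim: int = 50
    n_topics: int = 8
    topic_coherence: float = 0.8

    # atlas
    n_parcels_per_hemi: int = 175
    spatial_corr_length: float = 0.3  # radians; 0 -> spatially white fields
    gradient_range: Tuple[float, float] = (0.0, 1.0)

    # neural responses
    n_subjects: int = 20
    subj_sd: float = 1.0
    trial_sd: float = 1.0
    ar1_phi: float = 0.4
    tr: float = 2.0

    seed: int = 0

    def validate(self) -> "SimConfig":
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        slo, shi = self.sentence_length_range
        if not (1 <= slo <= shi):
            raise ValueError(f"invalid sentence_length_range {self.sentence_length_range}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.spatial_corr_length < 0:
            raise ValueError("spatial_corr_length must be >= 0")
        if not abs(self.ar1_phi) < 1:
            raise ValueError("|ar1_phi| must be < 1")
        if not 0 <= self.topic_coherence <= 1:
            raise ValueError("topic_coherence must be in [0, 1]")
        if self.n_parcels_per_hemi < 10:
            raise ValueError("need at least 10 parcels per hemisphere")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        g0, g1 = self.gradient_range
        if not g0 < g1:
            raise ValueError("gradient_range must be increasing")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueProfile:
    """Ground-truth gradient profile of one parameter's parcel sensitivity.

    shape='linear'  : sensitivity = intercept + slope * g
    shape='step2/3' : sensitivity = levels[bin(g)]   (equal-count bins)
    shape='null'    : sensitivity = intercept everywhere
    On top of the deterministic shape, a zero-mean Gaussian field with
    exponential spatial covariance (sd `noise_sd`, length scale from
    SimConfig.spatial_corr_length) is added.
    """

    parameter: str
    shape: str = "linear"
    intercept: float = 0.0
    slope: float = 0.0
    levels: Optional[Sequence[float]] = None
    noise_sd: float = 0.0

    def validate(self) -> "TrueProfile":
        if self.shape not in ("linear", "step2", "step3", "null"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.shape.startswith("step"):
            k = int(self.shape[-1])
            if self.levels is None or len(self.levels) != k:
                raise ValueError(f"shape {self.shape} requires exactly {k} level values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return self
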