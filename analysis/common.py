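"""Study conditions shared by the numbered analysis drivers.

One synthetic sentence-reading study: ~60 sentences of 9-15 words over a
Zipf lexicon, a 350-parcel mirrored spherical atlas with a smooth
unimodal-to-heteromodal gradient, and MEG-style trial responses in which
the three word-level parameters (length, OLD20, log frequency) grow more
effective towards the sensory end of the gradient while the two contextual
parameters (semantic similarity, sentence position) grow more effective
towards the heteromodal end — the pattern the pipeline is built to detect.
"""

from pathlib import Path

import gradlex as gx

STUDY_SEED = 20260401
N_PERM = 500

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "study"

WORD_PARAMS = ("length", "old20", "logfreq")
CONTEXT_PARAMS = ("semsim", "position")


def study_config() -> gx.SimConfig:
    return gx.SimConfig(
        n_words=2000,
        n_sentences=60,
        n_parcels_per_hemi=175,  # 350 parcels, the MEG-style atlas size
        n_subjects=12,
        spatial_corr_length=0.3,
        subj_sd=1.0,
        trial_sd=1.0,
        seed=STUDY_SEED,
    )


def true_profiles() -> dict:
    profiles = {}
    for p in WORD_PARAMS:
        profiles[p] = gx.TrueProfile(p, "linear", intercept=1.0, slope=-1.0, noise_sd=0.3)
    for p in CONTEXT_PARAMS:
        profiles[p] = gx.TrueProfile(p, "linear", intercept=0.0, slope=1.0, noise_sd=0.3)
    return profiles


def get_study() -> gx.SyntheticStudy:
    """Regenerate the study deterministically from its seed."""
    return gx.make_study(study_config(), true_profiles())
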