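"""Synthetic-data generator: determinism, marginal laws, spatial structure."""

import numpy as np
import pandas as pd
import pytest

import gradlex as gx
from gradlex._rng import substream
from gradlex.synth import gaussian_field, step_levels


class TestLexicon:
    def test_seed_determinism(self, tiny_cfg):
        a = gx.simulate_lexicon(tiny_cfg)
        b = gx.simulate_lexicon(tiny_cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zipf_slope_recovered_by_ols(self):
        cfg = gx.SimConfig(n_words=5000, zipf_exponent=1.0, seed=1)
        lex = gx.simulate_lexicon(cfg)
        ranks = np.arange(1, cfg.n_words + 1)
        sel = slice(9, 1000)  # ranks 10..1000
        slope = np.polyfit(np.log(ranks[sel]), np.log(lex.counts[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_degenerate_length_range(self):
        cfg = gx.SimConfig(n_words=100, length_range=(4, 4), seed=2)
        lex = gx.simulate_lexicon(cfg)
        assert all(len(w) == 4 for w in lex.words)

    def test_words_unique_and_lengths_bounded(self, tiny_lexicon, tiny_cfg):
        lo, hi = tiny_cfg.length_range
        assert len(set(tiny_lexicon.words)) == tiny_cfg.n_words
        assert all(lo <= len(w) <= hi for w in tiny_lexicon.words)

    def test_alphabet_capacity_failure(self):
        cfg = gx.SimConfig(n_words=27, length_range=(1, 1), seed=0)
        with pytest.raises(ValueError, match="alphabet too small"):
            gx.simulate_lexicon(cfg)


class TestEmbeddings:
    def test_unit_norm(self, tiny_embeddings):
        vecs = tiny_embeddings.table[tiny_embeddings.vector_columns].to_numpy()
        assert np.abs(np.linalg.norm(vecs, axis=1) - 1.0).max() < 1e-9

    def test_full_coherence_collapses_topics(self, tiny_lexicon):
        cfg = gx.SimConfig(n_words=400, topic_coherence=1.0, n_topics=4, seed=5)
        emb = gx.simulate_embeddings(tiny_lexicon, cfg)
        t = emb.table["topic"].to_numpy()
        vecs = emb.table[emb.vector_columns].to_numpy()
        same = t[:100, None] == t[None, :100]
        cos = vecs[:100] @ vecs[:100].T
        assert np.abs(cos[same] - 1.0).max() < 1e-9

    def test_within_topic_cosine_exceeds_between(self, rng):
        cfg = gx.SimConfig(
            n_words=600, topic_coherence=0.8, n_topics=4, embed_dim=50, seed=6
        )
        lex = gx.simulate_lexicon(cfg)
        emb = gx.simulate_embeddings(lex, cfg)
        t = emb.table["topic"].to_numpy()
        vecs = emb.table[emb.vector_columns].to_numpy()
        i = rng.integers(0, len(t), 1000)
        j = rng.integers(0, len(t), 1000)
        ok = i != j
        cos = (vecs[i] * vecs[j]).sum(1)[ok]
        same = (t[i] == t[j])[ok]
        assert cos[same].mean() > cos[~same].mean()


class TestSentences:
    def test_lengths_within_range(self, tiny_events, tiny_cfg):
        lo, hi = tiny_cfg.sentence_length_range
        lengths = tiny_events.groupby("sentence_id")["position"].max()
        assert lengths.between(lo, hi).all()

    def test_onsets_monotone_with_durations(self, tiny_events):
        for _, sent in tiny_events.groupby("sentence_id"):
            on = sent["onset"].to_numpy()
            assert (np.diff(on) > 0).all()

    def test_full_fidelity_keeps_sentence_topic(self, tiny_lexicon):
        cfg = gx.SimConfig(n_words=400, topic_fidelity=1.0, n_sentences=10, seed=9)
        emb = gx.simulate_embeddings(tiny_lexicon, cfg)
        ev = gx.simulate_sentences(tiny_lexicon, emb, cfg)
        content = ev[ev["is_content"]]
        word_topic = content["word"].map(emb.topic_of)
        assert (word_topic.to_numpy() == content["topic"].to_numpy()).all()

    def test_fidelity_raises_semantic_similarity(self):
        sims = {}
        for fid in (0.5, 0.95):
            cfg = gx.SimConfig(
                n_words=500, n_sentences=200, topic_fidelity=fid,
                topic_coherence=0.9, seed=13,
            )
            lex = gx.simulate_lexicon(cfg)
            emb = gx.simulate_embeddings(lex, cfg)
            ev = gx.simulate_sentences(lex, emb, cfg)
            feats = gx.build_feature_table(ev, lex, emb)
            sims[fid] = feats.loc[feats["included"], "semsim"].mean()
        assert sims[0.95] > sims[0.5]

    def test_duration_tracks_word_length(self, tiny_events):
        r = np.corrcoef(tiny_events["word"].str.len(), tiny_events["duration"])[0, 1]
        assert r > 0.7  # length-yoked presentation durations


class TestAtlas:
    def test_distinct_centroids(self, tiny_atlas):
        for hemi in "LR":
            c = tiny_atlas.centroids(hemi)
            d2 = ((c[:, None] - c[None]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            assert d2.min() > 0

    def test_gradient_spans_range_exactly(self, tiny_atlas, tiny_cfg):
        g = tiny_atlas.gradient
        lo, hi = tiny_cfg.gradient_range
        assert g.min() == pytest.approx(lo, abs=1e-12)
        assert g.max() == pytest.approx(hi, abs=1e-12)

    def test_mirror_symmetric_centroids(self, tiny_atlas):
        left = tiny_atlas.centroids("L")
        right = tiny_atlas.centroids("R")
        assert np.allclose(left * np.array([-1, 1, 1]), right)

    def test_gradient_spatial_correlogram_decays(self):
        cfg = gx.SimConfig(n_parcels_per_hemi=150, spatial_corr_length=0.3, seed=21)
        atlas = gx.simulate_atlas(cfg)
        c = atlas.centroids("L")
        g = atlas.gradient[atlas.hemi_index("L")]
        gc = g - g.mean()
        geo = np.arccos(np.clip(c @ c.T, -1, 1))
        prod = np.outer(gc, gc) / gc.var()
        iu = np.triu_indices_from(geo, k=1)
        near = prod[iu][geo[iu] < 0.5]
        far = prod[iu][geo[iu] > 2.0]
        assert near.mean() > far.mean()


class TestEffectProfile:
    def test_noise_free_linear_is_exact(self, tiny_atlas, tiny_cfg):
        prof = gx.TrueProfile("length", "linear", intercept=0.0, slope=2.0, noise_sd=0.0)
        s = gx.simulate_effect_profile(tiny_atlas, prof, tiny_cfg)
        assert np.allclose(s, 2.0 * tiny_atlas.gradient)

    def test_step_shape_uses_supplied_levels(self, tiny_atlas, tiny_cfg):
        prof = gx.TrueProfile("length", "step3", levels=(0.0, 1.0, 5.0), noise_sd=0.0)
        s = gx.simulate_effect_profile(tiny_atlas, prof, tiny_cfg)
        assert set(np.unique(s)) == {0.0, 1.0, 5.0}
        assert np.allclose(s, step_levels(tiny_atlas.gradient, (0.0, 1.0, 5.0)))

    def test_null_profile_uncorrelated_with_gradient(self):
        cfg = gx.SimConfig(n_parcels_per_hemi=250, spatial_corr_length=0.3, seed=30)
        atlas = gx.simulate_atlas(cfg)
        prof = gx.TrueProfile("x", "null", intercept=0.0, noise_sd=1.0)
        rng = substream(77, "null-profile")
        corrs = [
            np.corrcoef(
                gx.simulate_effect_profile(atlas, prof, cfg, rng=rng), atlas.gradient
            )[0, 1]
            for _ in range(100)
        ]
        assert abs(np.mean(corrs)) < 0.05

    def test_spatial_noise_correlogram(self, rng):
        cfg = gx.SimConfig(n_parcels_per_hemi=100, spatial_corr_length=0.3, seed=31)
        atlas = gx.simulate_atlas(cfg)
        xyz = atlas.folded_centroids()
        d = np.sqrt(np.maximum(0, ((xyz[:, None] - xyz[None]) ** 2).sum(-1)))
        fields = np.stack([gaussian_field(xyz, 0.3, 1.0, rng) for _ in range(200)])
        cov = np.cov(fields.T)
        iu = np.triu_indices_from(d, k=1)
        near = cov[iu][d[iu] < 0.2].mean()
        far = cov[iu][d[iu] > 1.5].mean()
        assert near > far + 0.2

    def test_white_noise_when_corr_length_zero(self, rng):
        xyz = gx.simulate_atlas(gx.SimConfig(n_parcels_per_hemi=50, seed=1)).folded_centroids()
        f = gaussian_field(xyz, 0.0, 2.0, rng)
        assert f.std() == pytest.approx(2.0, rel=0.2)


class TestMegTrials:
    def test_noise_free_equals_linear_predictor(self, tiny_features, tiny_sensitivities):
        cfg = gx.SimConfig(n_parcels_per_hemi=30, n_subjects=3, subj_sd=0.0, trial_sd=0.0, seed=3)
        tr = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, cfg)
        inc = tiny_features[tiny_features["included"]]
        x = np.column_stack([inc[f"z_{p}"] for p in tiny_sensitivities])
        smaps = np.column_stack([tiny_sensitivities[p] for p in tiny_sensitivities])
        expected = x @ smaps.T
        for s in range(3):
            assert np.allclose(tr.activation[s], expected)

    def test_between_subject_variance_matches_subj_sd(self, tiny_features, tiny_sensitivities):
        cfg = gx.SimConfig(
            n_parcels_per_hemi=30, n_subjects=200, subj_sd=1.5, trial_sd=0.3, seed=41
        )
        tr = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, cfg)
        # per-subject mean over trials and parcels isolates the random intercept
        subj_means = tr.activation.mean(axis=(1, 2))
        assert subj_means.var(ddof=1) == pytest.approx(cfg.subj_sd**2, rel=0.3)

    def test_seed_determinism(self, tiny_cfg, tiny_features, tiny_sensitivities):
        a = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, tiny_cfg)
        b = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, tiny_cfg)
        assert np.array_equal(a.activation, b.activation)

    def test_mismatched_parameter_sets_fail(self, tiny_cfg, tiny_features, tiny_atlas):
        bad = {"not_a_parameter": np.zeros(tiny_atlas.n_parcels)}
        with pytest.raises(ValueError, match="not_a_parameter"):
            gx.simulate_meg_trials(tiny_features, bad, tiny_cfg)


class TestBold:
    def test_residual_lag1_autocorrelation(self, tiny_events, tiny_features, tiny_atlas):
        cfg = gx.SimConfig(
            n_parcels_per_hemi=30, n_subjects=1, trial_sd=1.0, ar1_phi=0.5, seed=55
        )
        zero = {p: np.zeros(tiny_atlas.n_parcels) for p in gx.PARAMETERS}
        _, series = gx.simulate_bold_study(tiny_events, tiny_features, zero, cfg)
        y = series[0]  # pure AR(1) noise: no signal anywhere
        r1 = np.mean(
            [np.corrcoef(y[:-1, j], y[1:, j])[0, 1] for j in range(y.shape[1])]
        )
        assert r1 == pytest.approx(0.5, abs=0.1)

    def test_no_events_gives_zero_mean_noise(self, tiny_events, tiny_features):
        cfg = gx.SimConfig(n_parcels_per_hemi=30, n_subjects=1, trial_sd=1.0, seed=56)
        empty_ev = tiny_events.iloc[0:0]
        empty_f = tiny_features.iloc[0:0]
        zero = {p: np.zeros(60) for p in gx.PARAMETERS}
        design, series = gx.simulate_bold_study(empty_ev, empty_f, zero, cfg)
        task = design.frame[[c for c in design.frame.columns if c.startswith("ev_")]]
        assert (task.to_numpy() == 0).all()
        assert abs(series[0].mean()) < 0.3
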