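"""Effect-map estimation: design matrix, first-level GLM, group z, mass LMMs."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gradlex as gx
from gradlex.effects import Z_CAP, double_gamma_hrf


def _single_event_frame(onset, duration, word="abcdef", position=7, content=True):
    ev = pd.DataFrame(
        {
            "sentence_id": [0],
            "order": [0],
            "is_complex": [0],
            "topic": [0],
            "word": [word],
            "position": [position],
            "pos_tag": ["noun" if content else "other"],
            "is_content": [content],
            "onset": [onset],
            "duration": [duration],
            "occurrence_id": [0],
            "sentence_onset": [onset],
            "sentence_duration": [duration],
        }
    )
    ev.index.name = "event"
    return ev


class TestDesignMatrix:
    def test_single_event_matches_convolution_oracle(self):
        """One 1-s event: column equals the direct numerical convolution of a
        boxcar with the double-gamma HRF, evaluated independently."""
        tr, dt = 2.0, 0.1
        ev = _single_event_frame(onset=10.0, duration=0.5)
        feats = ev.copy()
        feats["included"] = False
        design = gx.build_design_matrix(
            ev, feats, tr=tr, n_scans=40, ev_scheme="fixed_1s", dt=dt, check_rank=False
        )
        col = design.frame["pos_noun"].to_numpy()

        # oracle: explicit discrete convolution sum on the fine grid
        fine_t = np.arange(0, 40 * tr + 32.0, dt)
        box = ((fine_t >= 10.0) & (fine_t < 11.0)).astype(float)  # fixed 1 s
        hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))
        oracle_fine = np.array(
            [sum(box[j] * hrf[i - j] for j in range(max(0, i - len(hrf) + 1), i + 1)) * dt
             for i in range(len(fine_t))]
        )
        scan_idx = np.round(np.arange(40) * tr / dt).astype(int)
        assert np.abs(col - oracle_fine[scan_idx]).max() < 1e-10

    def test_superposition_of_well_separated_events(self):
        tr = 2.0
        e1 = _single_event_frame(onset=10.0, duration=1.0)
        e2 = _single_event_frame(onset=90.0, duration=1.0)
        both = pd.concat([e1, e2], ignore_index=True)
        both.index.name = "event"
        kw = dict(tr=tr, n_scans=80, check_rank=False)
        f = lambda ev: ev.assign(included=False)
        c1 = gx.build_design_matrix(e1, f(e1), **kw).frame["pos_noun"].to_numpy()
        c2 = gx.build_design_matrix(e2, f(e2), **kw).frame["pos_noun"].to_numpy()
        c12 = gx.build_design_matrix(both, f(both), **kw).frame["pos_noun"].to_numpy()
        assert np.allclose(c12, c1 + c2, atol=1e-12)

    def test_no_events_zero_task_columns(self):
        ev = _single_event_frame(0, 1).iloc[0:0]
        design = gx.build_design_matrix(ev, ev.assign(included=False), tr=2.0, n_scans=30)
        task = design.frame[[c for c in design.frame.columns if c.startswith("ev_")]]
        assert (task.to_numpy() == 0).all()

    def test_parametric_ev_uses_included_values_only(self, tiny_events, tiny_features):
        design = gx.build_design_matrix(tiny_events, tiny_features, tr=2.0)
        assert set(design.param_columns) == set(gx.PARAMETERS)
        assert design.frame["constant"].eq(1).all()
        assert any(c.startswith("drift_") for c in design.frame.columns)
        assert any(c.startswith("d_ev_") for c in design.frame.columns)

    def test_rank_deficiency_reported(self, tiny_events, tiny_features):
        ev = tiny_events.copy()
        ev["pos_tag"] = "noun"  # all three other POS columns become all-zero;
        # duplicate sentences make complex/simple collinear with fixation
        ev["is_complex"] = 1
        design = gx.build_design_matrix(ev, tiny_features, tr=2.0, check_rank=False)
        x = design.frame
        assert np.linalg.matrix_rank(x.to_numpy()) <= x.shape[1]


class TestFirstLevel:
    def test_doubling_amplitude_doubles_coefficients(self, tiny_events, tiny_features, rng):
        design = gx.build_design_matrix(tiny_events, tiny_features, tr=2.0)
        y = rng.normal(size=(design.n_scans, 4))
        a = gx.fit_first_level(y, design)
        b = gx.fit_first_level(2 * y, design)
        pd.testing.assert_frame_equal(2 * a.coef, b.coef)

    def test_null_ev_t_statistics_follow_student_t(self, tiny_events, tiny_features, rng):
        design = gx.build_design_matrix(tiny_events, tiny_features, tr=2.0)
        y = rng.normal(size=(design.n_scans, 200))  # white noise: every EV is null
        res = gx.fit_first_level(y, design)
        t = (res.coef["ev_length"] / res.se["ev_length"]).to_numpy()
        ks = stats.kstest(t, stats.t(df=res.dof).cdf)
        assert ks.pvalue > 0.01

    def test_nonfinite_series_rejected(self, tiny_events, tiny_features):
        design = gx.build_design_matrix(tiny_events, tiny_features, tr=2.0)
        y = np.zeros((design.n_scans, 2))
        y[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            gx.fit_first_level(y, design)


class TestGroupZ:
    def test_identical_positive_coefficients_capped(self):
        c = np.ones((5, 10))
        with pytest.warns(RuntimeWarning):
            em = gx.group_z(c, "length")
        assert (em.values == Z_CAP).all()

    def test_sign_equivariance(self, rng):
        c = rng.normal(size=(12, 50))
        a = gx.group_z(c, "length").values
        b = gx.group_z(-c, "length").values
        assert np.allclose(a, -b)

    def test_null_coefficients_give_standard_normal_map(self, rng):
        c = rng.normal(size=(20, 500))
        z = gx.group_z(c, "length").values
        assert abs(z.mean()) < 0.1
        assert z.std() == pytest.approx(1.0, abs=0.15)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            gx.group_z(np.ones((2, 5)), "length")


class TestVertexAggregation:
    def test_uniform_full_coverage(self):
        labels = np.repeat([0, 1, 2], 10)
        vals, inc = gx.aggregate_vertices_to_parcels(
            np.full(30, 3.5), labels, np.ones(30)
        )
        assert np.allclose(vals, 3.5) and inc.all()

    def test_coverage_threshold_boundary(self):
        labels = np.zeros(100, int)
        w = np.zeros(100)
        w[:24] = 1.0  # 24% coverage -> excluded
        _, inc = gx.aggregate_vertices_to_parcels(np.ones(100), labels, w, n_parcels=1)
        assert not inc[0]
        w[:26] = 1.0  # 26% -> included
        _, inc = gx.aggregate_vertices_to_parcels(np.ones(100), labels, w, n_parcels=1)
        assert inc[0]

    def test_weight_threshold_boundary(self):
        labels = np.zeros(4, int)
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        w = np.array([0.74, 0.76, 1.0, 1.0])  # first vertex dropped
        out, inc = gx.aggregate_vertices_to_parcels(vals, labels, w, n_parcels=1)
        assert inc[0] and out[0] == pytest.approx((2 + 4 + 8) / 3)

    def test_empty_parcel_excluded_not_error(self):
        labels = np.array([0, 0, 2])
        vals, inc = gx.aggregate_vertices_to_parcels(
            np.ones(3), labels, np.ones(3), n_parcels=3
        )
        assert not inc[1] and np.isnan(vals[1])


class TestMassLmm:
    def test_noise_free_identifiability(self, tiny_features, tiny_sensitivities):
        cfg = gx.SimConfig(
            n_parcels_per_hemi=30, n_subjects=4, subj_sd=0.0, trial_sd=0.0, seed=3
        )
        trials = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, cfg)
        maps = gx.fit_mass_lmm(trials, tiny_features)
        for p in gx.PARAMETERS:
            assert np.abs(maps[p].values - tiny_sensitivities[p]).max() < 1e-6

    def test_trial_permutation_invariance(self, tiny_trials, tiny_features):
        perm = np.random.default_rng(4).permutation(len(tiny_trials.trials))
        shuffled = gx.TrialActivationTable(
            activation=tiny_trials.activation[:, perm, :3],
            subjects=tiny_trials.subjects,
            trials=tiny_trials.trials[perm],
            parcel_ids=tiny_trials.parcel_ids[:3],
            window=tiny_trials.window,
        )
        orig = gx.TrialActivationTable(
            activation=tiny_trials.activation[:, :, :3],
            subjects=tiny_trials.subjects,
            trials=tiny_trials.trials,
            parcel_ids=tiny_trials.parcel_ids[:3],
            window=tiny_trials.window,
        )
        a = gx.fit_mass_lmm(orig, tiny_features)
        b = gx.fit_mass_lmm(shuffled, tiny_features)
        for p in gx.PARAMETERS:
            assert np.allclose(a[p].values, b[p].values, atol=1e-6)

    def test_zero_subject_variance_equals_ols(self, tiny_features, tiny_sensitivities):
        import statsmodels.api as sm

        from gradlex.effects import _lmm_design

        cfg = gx.SimConfig(
            n_parcels_per_hemi=30, n_subjects=6, subj_sd=0.0, trial_sd=1.0, seed=17
        )
        trials = gx.simulate_meg_trials(tiny_features, tiny_sensitivities, cfg)
        maps = gx.fit_mass_lmm(trials, tiny_features)
        x, names = _lmm_design(tiny_features, trials.trials, "length")
        x_full = np.tile(x, (len(trials.subjects), 1))
        j = 0  # check one parcel against plain least squares
        y = trials.activation[:, :, j].reshape(-1)
        ols = sm.OLS(y, x_full).fit()
        if maps["length"].flags["ols_fallback"][j]:
            assert maps["length"].values[j] == pytest.approx(
                ols.params[names.index("z_length")], abs=1e-12
            )
        else:  # near-boundary REML fit must still be numerically close to OLS
            assert maps["length"].values[j] == pytest.approx(
                ols.params[names.index("z_length")], abs=1e-3
            )

    def test_matches_lme4_oracle(self, tmp_path, rng):
        """Random-intercept REML fit agrees with lme4 on a small dataset."""
        n_subj, n_tr = 8, 40
        subject = np.repeat(np.arange(n_subj), n_tr)
        x = rng.normal(size=n_subj * n_tr)
        y = 0.7 * x + rng.normal(0, 1.2, n_subj)[subject] + rng.normal(size=len(x))
        df = pd.DataFrame({"y": y, "x": x, "subject": subject})
        csv = tmp_path / "toy.tsv"
        df.to_csv(csv, sep="\t", index=False)
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.delim("{csv}")
            m <- lmer(y ~ x + (1|subject), data=d, REML=TRUE)
            cat(sprintf("%.10f %.10f", fixef(m)["x"], sqrt(diag(vcov(m)))[2]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        est_r, se_r = map(float, out.stdout.split())

        import statsmodels.api as sm

        exog = np.column_stack([np.ones(len(x)), x])
        res = sm.MixedLM(y, exog, groups=subject).fit(reml=True)
        assert res.fe_params[1] == pytest.approx(est_r, abs=1e-5)
        assert res.bse_fe[1] == pytest.approx(se_r, abs=1e-4)

    def test_constant_predictor_named(self, tiny_trials, tiny_features):
        broken = tiny_features.copy()
        broken["z_old20"] = 0.0
        with pytest.raises(ValueError, match="z_old20"):
            gx.fit_mass_lmm(tiny_trials, broken)


class TestDurationControl:
    def test_confounded_duration_gives_identical_other_estimates(
        self, tiny_cfg, tiny_features, tiny_sensitivities
    ):
        feats = tiny_features.copy()
        feats["duration"] = 2.0 * feats["length"]  # perfectly confounded
        feats["z_duration"] = feats["z_length"]
        trials = gx.simulate_meg_trials(feats, tiny_sensitivities, tiny_cfg)
        primary = gx.fit_mass_lmm(trials, feats)
        control = gx.duration_control_refit(trials, feats)
        for p in ("old20", "logfreq", "semsim", "position"):
            assert np.allclose(primary[p].values, control[p].values, atol=1e-8)
        assert control["duration"].tag == "control"

    def test_control_swaps_length_for_duration(self, tiny_trials, tiny_features):
        control = gx.duration_control_refit(tiny_trials, tiny_features)
        assert "duration" in control and "length" not in control
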