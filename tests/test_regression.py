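"""Mixed-model engine, mass-univariate grids, FDR, model comparison and
point-estimate regressions."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prederr import behavior, erp, regression, synth
from prederr.regression import (ConvergenceError, compare_models,
                                condition_average_features, fdr_correct,
                                fit_lmm, mass_univariate_time,
                                mass_univariate_tfr,
                                point_estimate_regression, split_by_valence,
                                topography_windows,
                                valence_split_regression)
from prederr.synth import EpochsContainer
from prederr.tfr import tfr_transform

SFREQ = 250.0
TIMES = -0.2 + np.arange(301) / SFREQ


def _noise_epochs(n_per_group=40, n_groups=3, n_channels=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    data = rng.normal(size=(n, n_channels, len(TIMES))).astype(np.float32)
    events = pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(n_groups)],
                                    n_per_group),
        "trial_index": np.arange(n)})
    chans = tuple(["Fz", "Pz", "Cz", "FCz"][:n_channels])
    return EpochsContainer(data, TIMES, chans, SFREQ, events)


class TestFitLMM:
    def test_intercept_only_recovers_grand_mean(self):
        rng = np.random.default_rng(0)
        g = np.repeat(np.arange(4), 50)
        y = rng.normal(size=200) + np.array([0., 1., -1., 0.5])[g]
        fit = fit_lmm(y, None, g)
        assert fit.params.loc["intercept", "beta"] \
            == pytest.approx(y.mean(), abs=0.05)
        assert fit.n_groups == 4

    def test_slope_recovery_with_nominal_ci_coverage(self):
        """y = 2x + participant offset + noise: the fixed-effect CI covers
        the generating slope at ~95% across 100 seeded replicates."""
        from scipy import stats

        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = np.repeat(np.arange(6), 100)
            x = rng.normal(size=600)
            y = 2 * x + rng.normal(0, 1, 6)[g] + rng.normal(size=600)
            fit = fit_lmm(y, pd.DataFrame({"x": x}), g)
            row = fit.params.loc["x"]
            crit = stats.t.ppf(0.975, fit.dof_resid)
            hits += abs(row["beta"] - 2.0) <= crit * row["se"]
        assert hits >= 93

    def test_null_p_values_are_uniform(self):
        """Pure-noise responses yield uniformly distributed predictor
        p-values (KS test not rejecting at alpha = 0.01)."""
        from scipy import stats

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            g = np.repeat(np.arange(4), 50)
            x = rng.normal(size=200)
            y = rng.normal(0, 1, 4)[g] + rng.normal(size=200)
            pvals.append(fit_lmm(y, pd.DataFrame({"x": x}), g)
                         .params.loc["x", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_design_names_columns(self):
        g = np.repeat(np.arange(3), 20)
        x = np.arange(60, dtype=float)
        with pytest.raises(ValueError, match="b"):
            fit_lmm(np.ones(60), pd.DataFrame({"a": x, "b": 2 * x}), g)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            fit_lmm(np.ones(30), None, np.zeros(30))

    def test_matches_reference_lmer_fit(self, tmp_path):
        """ML fit, log-likelihood and AIC agree with lme4's lmer (REML off),
        which uses the same parameter count k = n_fixed + 2."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        g = np.repeat(np.arange(5), 40)
        x1, x2 = rng.normal(size=200), rng.normal(size=200)
        y = 1.0 + 2.0 * x1 - 0.5 * x2 + rng.normal(0, 1.5, 5)[g] \
            + rng.normal(size=200)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            f"suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            f"m <- lmer(y ~ x1 + x2 + (1|g), data=d, REML=FALSE);"
            f"cat(fixef(m), as.numeric(logLik(m)), AIC(m), sep=',')")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        b0, b1, b2, llf, aic = map(float, out.stdout.strip().split(","))
        fit = fit_lmm(y, df[["x1", "x2"]], g)
        assert fit.params.loc["intercept", "beta"] == pytest.approx(b0,
                                                                    abs=1e-4)
        assert fit.params.loc["x1", "beta"] == pytest.approx(b1, abs=1e-4)
        assert fit.params.loc["x2", "beta"] == pytest.approx(b2, abs=1e-4)
        assert fit.loglik == pytest.approx(llf, abs=1e-3)
        assert fit.aic == pytest.approx(aic, abs=1e-2)


class TestFDR:
    def test_hand_computed_step_up_example(self):
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),          # single p: q = p
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_degenerate_families(self, p, expected):
        np.testing.assert_allclose(fdr_correct(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_q_dominates_p_and_preserves_order(self, p):
        q = fdr_correct(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestMassUnivariateGrids:
    def test_time_grid_has_113_points_per_channel(self):
        ep = _noise_epochs()
        design = pd.DataFrame({"x": np.random.default_rng(0)
                               .normal(size=ep.n_trials)})
        res = mass_univariate_time(ep, design, channels=("Fz",))
        times = res.table.loc[res.table["predictor"] == "x", "time_s"]
        # non-converged points are skipped and counted, not silently lost
        assert len(times) + res.n_failed == 113
        assert times.min() >= 0.05 and times.max() <= 0.5 + 1e-9

    def test_q_dominates_p_and_intercept_excluded_from_family(self):
        ep = _noise_epochs()
        design = pd.DataFrame({"x": np.random.default_rng(1)
                               .normal(size=ep.n_trials)})
        res = mass_univariate_time(ep, design, channels=("Fz",), stride=8)
        tb = res.table
        assert tb.loc[tb["predictor"] == "intercept", "q"].isna().all()
        mask = tb["predictor"] == "x"
        assert (tb.loc[mask, "q"] >= tb.loc[mask, "p"] - 1e-12).all()

    def test_recovers_injected_effect_latency(self, clean_epochs,
                                              clean_features):
        """The RPE-magnitude coefficient time course at Fz peaks within
        12 ms of the injected FRN center on negative outcomes."""
        masks = split_by_valence(clean_epochs.events)
        sub = clean_epochs.select_trials(masks["negative"])
        design = clean_features.loc[
            masks["negative"],
            ["rpe_magnitude", "outcome_probability"]].reset_index(drop=True)
        res = mass_univariate_time(sub, design, channels=("Fz",),
                                   window=(0.1, 0.35))
        mag = res.table[res.table["predictor"] == "rpe_magnitude"]
        # the oscillatory burst has positive sidelobes; the most *negative*
        # coefficient marks the injected center
        peak = mag.loc[mag["beta"].idxmin()]
        assert abs(peak["time_s"] - 0.216) <= 0.012
        assert peak["beta"] < 0 and peak["q"] < 0.05

    def test_misaligned_design_rejected(self, clean_epochs):
        with pytest.raises(ValueError, match="align"):
            mass_univariate_time(clean_epochs,
                                 pd.DataFrame({"x": [1.0, 2.0]}))

    def test_tfr_grid_and_theta_delta_localization(self, clean_epochs,
                                                   clean_features):
        """Injected 6 Hz negative-outcome and 3 Hz positive-outcome bursts
        drive the strongest magnitude effects on evoked power into theta
        rows at Fz and delta rows at Pz respectively (power rises with the
        burst's amplitude, so both coefficients are positive)."""
        masks = split_by_valence(clean_epochs.events)
        out = {}
        for name, ch in [("negative", "Fz"), ("positive", "Pz")]:
            sub = clean_epochs.select_trials(masks[name]) \
                .select_channels([ch])
            design = clean_features.loc[
                masks[name], ["rpe_magnitude", "outcome_probability"]] \
                .reset_index(drop=True)
            cont = tfr_transform(sub)
            res = mass_univariate_tfr(cont, design, channels=(ch,),
                                      stride=10)
            mag = res.table[res.table["predictor"] == "rpe_magnitude"]
            out[name] = mag.loc[mag["beta"].idxmax()]
        assert 4.0 <= out["negative"]["freq_hz"] <= 8.0
        assert out["negative"]["beta"] > 0 and out["negative"]["q"] < 0.05
        assert 1.0 <= out["positive"]["freq_hz"] <= 4.0
        assert out["positive"]["beta"] > 0 and out["positive"]["q"] < 0.05


class TestTopography:
    def test_family_size_is_channels_by_predictors_by_windows(self):
        rng = np.random.default_rng(0)
        layout = synth.ChannelLayout.biosemi64()
        n = 90
        events = pd.DataFrame({
            "participant_id": np.repeat(["p0", "p1", "p2"], n // 3),
            "trial_index": np.arange(n)})
        data = rng.normal(size=(n, 64, len(TIMES))).astype(np.float32)
        ep = EpochsContainer(data, TIMES, layout.names, SFREQ, events)
        design = pd.DataFrame(rng.normal(size=(n, 4)),
                              columns=list("abcd"))
        res = topography_windows(ep, design)
        non_int = res.table[res.table["predictor"] != "intercept"]
        assert len(non_int) + res.n_failed * 4 == 64 * 3 * 4

    def test_injected_frontal_component_peaks_at_its_channel(self):
        comp = [c for c in synth.default_component_set()
                if c.label == "FRN"]
        layout = synth.ChannelLayout.biosemi64()
        rng = np.random.default_rng(3)
        n = 120
        trials = pd.DataFrame(dict(
            participant_id=np.repeat(["p0", "p1"], n // 2),
            trial_index=np.arange(n), block_index=0, difficulty="easy",
            is_training=False, tolerance_ms=100.0, rt_s=1.0,
            outcome="loss", reward_value=-1, iti_s=0.7))
        feats = pd.DataFrame({"rpe_magnitude": rng.uniform(0, 2, n)})
        ep = synth.synthesize_epochs(
            trials, feats, comp,
            synth.NoiseSpec(noise_sd=1.0, white_sd=0.5,
                            participant_intercept_sd=0.5),
            layout, seed=4)
        res = topography_windows(ep, feats, windows=((0.216, "frn"),))
        mag = res.table[res.table["predictor"] == "rpe_magnitude"]
        assert mag.loc[mag["beta"].abs().idxmax(), "channel"] == "Fz"

    def test_window_outside_epoch_rejected(self):
        ep = _noise_epochs()
        with pytest.raises(ValueError, match="window"):
            topography_windows(ep, pd.DataFrame(
                {"x": np.zeros(ep.n_trials)}), windows=((2.0, "late"),))


class TestModelComparison:
    def test_baseline_relative_aic_is_zero_and_deterministic(
            self, clean_epochs, clean_features):
        designs = {
            "RL": clean_features[behavior.RL_PREDICTORS],
            "RL_noMag": clean_features[behavior.RL_PREDICTORS]
            .drop(columns="rpe_magnitude")}
        a = compare_models(clean_epochs, designs, "Fz", [0.216])
        b = compare_models(clean_epochs, designs, "Fz", [0.216])
        pd.testing.assert_frame_equal(a, b)
        base = a.loc[a["variant"] == "baseline", "rel_aic"]
        np.testing.assert_array_equal(base, 0.0)

    def test_informative_model_beats_baseline_at_the_injected_peak(
            self, clean_epochs, clean_features):
        designs = {"RL": clean_features[behavior.RL_PREDICTORS]}
        out = compare_models(clean_epochs, designs, "Fz", [0.216])
        assert out.loc[out["variant"] == "RL", "rel_aic"].iloc[0] < 0

    def test_misaligned_variants_rejected(self, clean_epochs,
                                          clean_features):
        designs = {
            "RL": clean_features[behavior.RL_PREDICTORS],
            "bad": clean_features[behavior.RL_PREDICTORS].iloc[:-5]}
        with pytest.raises(ValueError, match="aligned"):
            compare_models(clean_epochs, designs, "Fz", [0.216])


class TestValenceSplit:
    def test_subset_definitions(self, clean_epochs):
        masks = split_by_valence(clean_epochs.events)
        conds = (clean_epochs.events["difficulty"] + " "
                 + clean_epochs.events["outcome"])
        neg = set(conds[masks["negative"]])
        pos = set(conds[masks["positive"]])
        assert neg == {"easy loss", "easy neutral", "hard loss"}
        assert pos == {"easy win", "hard win", "hard neutral"}

    def test_two_predictor_design_used(self, clean_epochs, clean_features):
        out = valence_split_regression(clean_epochs, clean_features,
                                       channels=("Fz",), stride=30)
        for res in out.values():
            preds = set(res.table["predictor"]) - {"intercept"}
            assert preds == {"rpe_magnitude", "outcome_probability"}

    def test_empty_subset_rejected(self, clean_epochs, clean_features):
        all_win = clean_epochs.events.assign(outcome="win")
        fake = EpochsContainer(clean_epochs.data, clean_epochs.times,
                               clean_epochs.channels, clean_epochs.sfreq,
                               all_win)
        with pytest.raises(ValueError, match="negative"):
            valence_split_regression(fake, clean_features,
                                     channels=("Fz",), stride=30)


@pytest.fixture(scope="module")
def tables(clean_epochs, clean_features):
    erps = erp.condition_average(clean_epochs)
    pest = erp.point_estimates(erps)
    feats = condition_average_features(clean_epochs.events, clean_features)
    return pest, feats


class TestPointEstimateRegression:
    def test_feature_table_is_participants_by_conditions(self, tables):
        _, feats = tables
        assert len(feats) == feats["participant_id"].nunique() * 6

    def test_amplitude_metric_uses_random_intercepts(self, tables):
        pest, feats = tables
        fit = point_estimate_regression(pest, feats, "frn_mean_uv")
        assert fit.n_groups == pest["participant_id"].nunique()
        assert "q" in fit.params.columns

    def test_latency_metric_uses_fixed_effects_only(self, tables):
        pest, feats = tables
        fit = point_estimate_regression(pest, feats, "frn_latency_norm_s")
        assert fit.sigma2_group == 0.0

    def test_missing_peak_to_peak_rows_dropped_listwise(self, tables):
        pest, feats = tables
        pest = pest.copy()
        pest.loc[pest.index[:3], "frn_p2p_uv"] = np.nan
        fit = point_estimate_regression(pest, feats, "frn_p2p_uv")
        assert fit.n_obs == pest["frn_p2p_uv"].notna().sum()

    def test_all_missing_metric_rejected(self, tables):
        pest, feats = tables
        pest = pest.copy()
        pest["frn_p2p_uv"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            point_estimate_regression(pest, feats, "frn_p2p_uv")
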