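import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lgnbinoc import synthetic_data as sd
from lgnbinoc.synthetic_data import (Condition, ExperimentDesign,
                                     SyntheticUnitConfig, archetype_config,
                                     simulate_experiment, simulate_trial,
                                     suppression_factor, unit_rate_function)


def _cfg(**kw):
    base = dict(unit_class="P", baseline_rate=5.0, r_max=40.0, c50=0.3,
                hill_n=2.0, supp_gamma=0.5, supp_c50_nd=0.4,
                supp_release_c50=0.4, phase_jitter_sd=0.0)
    base.update(kw)
    return SyntheticUnitConfig(**base)


class TestSuppressionFactor:
    def test_monocular_limit_is_exactly_one(self):
        cfg = _cfg()
        for cd in [0.0, 0.12, 0.9]:
            assert suppression_factor(cfg, cd, 0.0) == 1.0

    def test_half_release_at_release_c50_with_saturating_drive(self):
        # c_dom at the release semisaturation gives gate 1/2; c_nd -> 1 with
        # a steep Hill exponent saturates the drive, so S -> 1 - gamma/2
        cfg = _cfg(hill_n=50.0, supp_gamma=0.6)
        s = suppression_factor(cfg, cfg.supp_release_c50, 1.0)
        assert s == pytest.approx(1.0 - 0.6 / 2.0, abs=1e-6)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_monotone_antagonism(self, cd, cnd, cnd2):
        cfg = _cfg()
        lo, hi = sorted([cnd, cnd2])
        # non-increasing in non-dominant contrast
        assert suppression_factor(cfg, cd, hi) <= suppression_factor(cfg, cd, lo) + 1e-12
        # non-decreasing in dominant contrast
        assert (suppression_factor(cfg, min(cd + 0.1, 1.0), hi)
                >= suppression_factor(cfg, cd, hi) - 1e-12)


class TestRateFunction:
    def test_no_drive_gives_flat_baseline(self):
        lam = unit_rate_function(_cfg(), Condition(0.0, 0.0))
        np.testing.assert_allclose(lam, 5.0)

    def test_rate_never_negative_and_f1_amplitude_follows_crf(self):
        cfg = _cfg(supp_gamma=0.0)
        for c in [0.1, 0.3, 0.9]:
            lam = unit_rate_function(cfg, Condition(c, 0.0))
            assert lam.min() >= 0
            expected_peak = 5.0 + sd.naka_rushton(c, 40.0, 0.3, 2.0)
            assert lam.max() == pytest.approx(expected_peak, rel=1e-3)

    def test_doubling_waveform_fullwave_rectified(self):
        cfg = _cfg(doubling=True)
        lam = unit_rate_function(cfg, Condition(0.9, 0.0, chromatic_axis="L-M"))
        # full-wave rectification: rate peaks twice per drift cycle
        above = lam > lam.mean()
        n_bursts = int(((~above[:-1]) & above[1:]).sum())
        assert n_bursts == pytest.approx(8, abs=1)  # 2 per cycle x 4 cycles


class TestSimulateTrial:
    def test_zero_rate_gives_empty_train(self):
        cfg = _cfg(baseline_rate=0.0, r_max=0.0)
        spikes = simulate_trial(cfg, Condition(0.0, 0.0),
                                np.random.default_rng(0))
        assert len(spikes) == 0

    def test_constant_rate_poisson_mean(self):
        cfg = _cfg(baseline_rate=50.0, r_max=0.0)
        rng = np.random.default_rng(1)
        counts = [len(simulate_trial(cfg, Condition(0.0, 0.0), rng))
                  for _ in range(10_000)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 50.0) < 3 * se

    def test_zero_jitter_same_seed_is_deterministic(self):
        cfg = _cfg(phase_jitter_sd=0.0)
        a = simulate_trial(cfg, Condition(0.9, 0.0), np.random.default_rng(9))
        b = simulate_trial(cfg, Condition(0.9, 0.0), np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_times_inside_stimulation_window(self):
        cfg = _cfg()
        spikes = simulate_trial(cfg, Condition(0.9, 0.0, stim_duration=1000.0),
                                np.random.default_rng(2))
        assert np.all((spikes >= 0) & (spikes <= 1000.0))
        assert np.all(np.diff(spikes) >= 0)


class TestSimulateExperiment:
    def test_trial_counting(self):
        pop = [_cfg()]
        design = ExperimentDesign(contrasts_dom=[0.9], contrasts_nondom=[0.0, 0.9],
                                  trials_per_condition=12, include_blanks=False)
        spikes, trials, truth = simulate_experiment(pop, design, seed=0)
        assert len(trials.df) == 24

    def test_ground_truth_zero_for_monocular_rows(self):
        pop = [_cfg(supp_gamma=0.7)]
        design = ExperimentDesign(contrasts_dom=[0.12], contrasts_nondom=[0.0, 0.9],
                                  trials_per_condition=12)
        _, _, truth = simulate_experiment(pop, design, seed=0)
        mono = truth[truth["nondom_contrast"] == 0.0]
        assert (mono["true_modulation_amp"] == 0.0).all()
        binoc = truth[truth["nondom_contrast"] > 0.0]
        assert (binoc["true_modulation_amp"] < 0.0).all()

    def test_identical_seed_gives_identical_tables(self):
        pop = [archetype_config("M"), archetype_config("K")]
        design = ExperimentDesign(trials_per_condition=12)
        s1, t1, g1 = simulate_experiment(pop, design, seed=42)
        s2, t2, g2 = simulate_experiment(pop, design, seed=42)
        pd.testing.assert_frame_equal(s1.df, s2.df)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(g1, g2)

    def test_minimum_trial_rule_enforced(self):
        with pytest.raises(ValueError, match="12"):
            ExperimentDesign(trials_per_condition=8)


class TestInjectInstability:
    def test_scale_one_is_identity(self):
        pop = [_cfg()]
        design = ExperimentDesign(contrasts_dom=[0.9], contrasts_nondom=[0.0],
                                  trials_per_condition=20, include_blanks=False)
        spikes, trials, _ = simulate_experiment(pop, design, seed=1)
        out = sd.inject_instability(spikes, "u000", (5, 15), 1.0)
        pd.testing.assert_frame_equal(out.df, spikes.df)

    def test_scale_zero_empties_span(self):
        pop = [_cfg()]
        design = ExperimentDesign(contrasts_dom=[0.9], contrasts_nondom=[0.0],
                                  trials_per_condition=20, include_blanks=False)
        spikes, trials, _ = simulate_experiment(pop, design, seed=1)
        out = sd.inject_instability(spikes, "u000", (5, 15), 0.0,
                                    rng=np.random.default_rng(0))
        span_ids = set(spikes.trials_for_unit("u000")[5:15])
        assert not out.df["trial_id"].isin(span_ids).any()

    def test_span_out_of_range_raises(self):
        pop = [_cfg()]
        design = ExperimentDesign(contrasts_dom=[0.9], contrasts_nondom=[0.0],
                                  trials_per_condition=12, include_blanks=False)
        spikes, _, _ = simulate_experiment(pop, design, seed=1)
        with pytest.raises(IndexError):
            sd.inject_instability(spikes, "u000", (5, 99), 0.5)


class TestCalibratedPopulation:
    def test_generative_median_hits_target(self):
        rng = np.random.default_rng(4)
        pop = sd.calibrated_population(12, -12.0, pairs=[(0.12, 0.9)], rng=rng)
        tab = sd.expected_modulation_table(pop, [(0.12, 0.9)])
        med = tab["expected_measured_modulation"].median()
        assert med == pytest.approx(-12.0, abs=0.3)

    def test_f1_grows_with_contrast_following_crf(self):
        # empirical F1 of a linear unit tracks the configured Naka-Rushton
        from lgnbinoc.spectral import f1_from_binaries
        cfg = _cfg(supp_gamma=0.0, phase_jitter_sd=None)
        rng = np.random.default_rng(5)
        means = []
        for c in [0.12, 0.34, 0.9]:
            B = sd.simulate_binaries(cfg, Condition(c, 0.0), 60, rng)
            means.append(f1_from_binaries(B, 4.0).mean)
        assert means[0] < means[1] < means[2]
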