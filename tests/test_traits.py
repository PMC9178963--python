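"""SMR, MMR, aerobic scope, RMR binning, Q10 and condition factor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamresp import synthetic, traces as tr, traits
from conftest import make_series


class TestSMR:
    def test_uniform_series(self):
        smr, temp, n = traits.estimate_smr(make_series(np.full(100, 2.0)))
        assert smr == pytest.approx(2.0)
        assert n == 20

    def test_lowest_quintile_of_integers(self):
        smr, _, n = traits.estimate_smr(make_series(np.arange(1.0, 101.0)))
        assert n == 20
        assert smr == pytest.approx(10.5)  # mean of 1..20

    def test_count_rounds_half_up(self):
        assert traits.lowest_quantile_count(120) == 24
        assert traits.lowest_quantile_count(108) == 22  # round(21.6)
        assert traits.lowest_quantile_count(3) == 1

    def test_smr_temperature_from_same_entries(self):
        mo2 = np.arange(1.0, 11.0)
        temps = np.arange(10.0, 20.0)
        smr, temp, n = traits.estimate_smr(make_series(mo2, temps))
        assert n == 2
        assert temp == pytest.approx(10.5)  # temps of the two lowest rates

    def test_too_few_entries_rejected(self):
        with pytest.raises(ValueError):
            traits.estimate_smr(make_series([1.0, 2.0, 3.0, 4.0]))


class TestMMR:
    def test_max_and_location(self):
        mmr, t, _ = traits.estimate_mmr(make_series([3.0, 9.0, 5.0]))
        assert mmr == 9.0
        assert t == pytest.approx(180.0 + 600.0)  # second cycle midpoint

    def test_monotone_decay_first_entry(self):
        series = make_series(10.0 * np.exp(-0.1 * np.arange(20)) + 2.0)
        mmr, t, _ = traits.estimate_mmr(series)
        assert t == pytest.approx(180.0)
        assert mmr == pytest.approx(12.0)


class TestAerobicScope:
    def test_worked_example(self):
        aas, fas = traits.aerobic_scope(2.0, 10.0)
        assert (aas, fas) == (8.0, 5.0)

    def test_degenerate_scope(self):
        aas, fas = traits.aerobic_scope(2.0, 2.0)
        assert (aas, fas) == (0.0, 1.0)

    def test_nonpositive_smr_rejected(self):
        with pytest.raises(ValueError):
            traits.aerobic_scope(0.0, 5.0)

    @given(smr=st.floats(0.1, 10.0), mmr=st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_aas_equals_smr_times_fas_minus_one(self, smr, mmr):
        aas, fas = traits.aerobic_scope(smr, mmr)
        assert aas == pytest.approx(smr * (fas - 1.0), rel=1e-12, abs=1e-12)


class TestRMR:
    def test_single_bin_when_temps_tight(self):
        series = make_series(np.full(20, 2.0), np.full(20, 18.2))
        bins = traits.estimate_rmr(series, epoc_end_s=0.0)
        assert len(bins) == 1
        assert bins[0].temp_bin_c == 18.0
        assert bins[0].n == 20

    def test_sparse_bin_dropped(self):
        temps = np.array([18.0] * 3 + [20.0] * 2)
        series = make_series(np.full(5, 2.0), temps)
        bins = traits.estimate_rmr(series, epoc_end_s=0.0)
        assert [b.temp_bin_c for b in bins] == [18.0]

    def test_pre_epoc_entries_excluded(self):
        series = make_series(np.full(10, 2.0))
        bins = traits.estimate_rmr(series, epoc_end_s=3000.0)
        assert bins[0].n == 5  # only entries after 3000 s

    def test_no_post_epoc_entries_empty(self):
        series = make_series(np.full(5, 2.0))
        assert traits.estimate_rmr(series, epoc_end_s=1e9) == []

    def test_diurnal_temperature_range_bin_count(self):
        # noiseless diurnal span 16.6-20.0 degC -> at most 4 integer bins
        profile = synthetic.diurnal_profile(18.3, amplitude_c=1.7)
        t = np.arange(0, 18 * 3600.0, 600.0)
        temps = profile(t)
        series = make_series(np.full(t.size, 2.0), temps)
        bins = traits.estimate_rmr(series, epoc_end_s=0.0)
        assert 1 <= len(bins) <= 4


class TestQ10:
    @pytest.mark.parametrize(
        "r1,r2,t1,t2,expected",
        [(1.0, 2.0, 15.0, 25.0, 2.0), (1.3, 1.3, 10.0, 20.0, 1.0),
         (1.0, 1.5, 17.0, 22.0, 2.25)],
    )
    def test_worked_examples(self, r1, r2, t1, t2, expected):
        assert traits.q10(r1, r2, t1, t2).q10 == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            traits.q10(0.0, 1.0, 10.0, 20.0)
        with pytest.raises(ValueError):
            traits.q10(1.0, 1.0, 15.0, 15.0)

    def test_chaining_consistency(self):
        # segment rates generated from one true Q10 chain geometrically
        q_true, r1 = 2.4, 1.1
        r2 = r1 * q_true ** ((19.0 - 12.0) / 10.0)
        r3 = r2 * q_true ** ((25.0 - 19.0) / 10.0)
        assert traits.q10(r1, r3, 12.0, 25.0).q10 == pytest.approx(q_true)


class TestConditionFactor:
    def test_worked_examples(self):
        assert traits.condition_factor(10.0, 100.0) == pytest.approx(1.0)
        assert traits.condition_factor(22.8, 130.2) == pytest.approx(1.033, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            traits.condition_factor(0.0, 100.0)


class TestMassScaling:
    def test_exact_isometric_cohort(self):
        mass = np.linspace(0.015, 0.03, 24)
        rate = 5.0 * mass  # exponent exactly 1
        res = traits.mass_scaling_check(rate, mass)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert not res.mass_correction_needed

    def test_allometric_recovery_monte_carlo(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            mass = rng.uniform(0.015, 0.03, 24)
            rate = 2.0 * mass**0.85 * np.exp(rng.normal(0, 0.05, 24))
            res = traits.mass_scaling_check(rate, mass)
            hits += abs(res.slope - 0.85) <= 0.1
        assert hits / n_rep >= 0.90

    def test_two_fish_rejected(self):
        with pytest.raises(ValueError):
            traits.mass_scaling_check([1.0, 2.0], [0.02, 0.03])

    def test_equal_masses_rejected(self):
        with pytest.raises(ValueError):
            traits.mass_scaling_check([1.0, 1.1, 1.2], [0.02, 0.02, 0.02])


class TestNoiselessRecoveryOfTruth:
    """Round-trip invariants: simulator -> pipeline recovers ground truth."""

    def test_smr_within_one_percent_post_epoc(self, noiseless_trial):
        trace, gt = noiseless_trial
        series = tr.build_mo2_series(
            trace, tr.CyclePlan(), tr.BackgroundModel(0.0, 0.0), gt.mass_kg
        )
        smr, _, _ = traits.estimate_smr(series)
        assert smr == pytest.approx(2.0, rel=0.01)

    def test_smr_rmr_mmr_ordering(self, noiseless_trial):
        trace, gt = noiseless_trial
        series = tr.build_mo2_series(
            trace, tr.CyclePlan(), tr.BackgroundModel(0.0, 0.0), gt.mass_kg
        )
        smr, _, _ = traits.estimate_smr(series)
        mmr, _, _ = traits.estimate_mmr(series)
        bins = traits.estimate_rmr(series, epoc_end_s=3 * 3600.0)
        assert bins
        for b in bins:
            assert smr <= b.rmr + 1e-9 <= mmr

    def test_q10_recovered_exactly_from_two_treatments(self, noiseless_truth):
        design = synthetic.TrialDesign(
            duration_h=3.0, sample_interval_s=5.0, noise_sd=0.0,
            background_fraction=0.0,
        )
        rates = {}
        for temp in (18.0, 23.0):
            truth = synthetic.SimFishTruth(
                "q", 20.0, 126.0, smr_ref=2.0, t_ref_c=18.0, q10_true=2.3,
                epoc_magnitude=0.0, epoc_rate_k=0.1,
                ctmax_true_mean=32.0, ctmax_true_sd=0.0,
            )
            trace, gt = synthetic.simulate_trial(
                truth, design, synthetic.constant_profile(temp)
            )
            series = tr.build_mo2_series(
                trace, tr.CyclePlan(), tr.BackgroundModel(0.0, 0.0), gt.mass_kg
            )
            bins = traits.estimate_rmr(series, epoc_end_s=0.0)
            rates[temp] = bins[0].rmr
        q = traits.q10(rates[18.0], rates[23.0], 18.0, 23.0)
        assert q.q10 == pytest.approx(2.3, rel=1e-6)
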