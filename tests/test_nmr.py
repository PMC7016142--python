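"""Intensity-ratio, exponential-fit, TRACT and PRE analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condensate_metrics.nmr import (
    DecaySeries,
    FitError,
    PeakTable,
    PRERecord,
    fit_exponential,
    intensity_ratio_profile,
    pre_delta_r2,
    tract_eta,
)
from condensate_metrics.synthetic import DecayParams, gen_decay_series, gen_peak_pair


def make_table(ids, intensities, noise):
    return PeakTable(pd.DataFrame({
        "residue_id": ids,
        "residue_name": ["X"] * len(ids),
        "intensity": intensities,
        "noise": noise,
    }))


class TestIntensityRatioProfile:
    def test_identical_tables_give_unit_ratio_with_sqrt2_over_snr_sigma(self):
        snr = 50.0
        table = make_table([1, 2, 3], [100.0] * 3, [100.0 / snr] * 3)
        profile = intensity_ratio_profile(table, table)
        assert profile.ratio.to_numpy() == pytest.approx([1.0] * 3)
        assert profile.sigma.to_numpy() == pytest.approx([np.sqrt(2.0) / snr] * 3)

    def test_hand_computed_sigma(self):
        num = make_table([7], [50.0], [1.0])
        den = make_table([7], [100.0], [2.0])
        profile = intensity_ratio_profile(num, den)
        assert profile.ratio.iloc[0] == pytest.approx(0.5)
        assert profile.sigma.iloc[0] == pytest.approx(0.5 * np.sqrt(0.0004 + 0.0004))

    def test_peak_below_noise_multiple_is_flagged_broadened(self):
        num = make_table([1, 2], [100.0, 2.0], [1.0, 1.0])
        den = make_table([1, 2], [100.0, 100.0], [1.0, 1.0])
        profile = intensity_ratio_profile(num, den).set_index("residue_id")
        assert profile.at[1, "status"] == "ok"
        assert profile.at[2, "status"] == "broadened"
        assert pd.isna(profile.at[2, "ratio"])

    def test_unmatched_residues_reported_missing(self):
        num = make_table([1, 2], [50.0, 60.0], [1.0, 1.0])
        den = make_table([2, 3], [100.0, 100.0], [1.0, 1.0])
        profile = intensity_ratio_profile(num, den).set_index("residue_id")
        assert profile.at[1, "status"] == "missing_denominator"
        assert profile.at[3, "status"] == "missing_numerator"
        assert profile.at[2, "status"] == "ok"

    def test_no_shared_residues_raises(self):
        with pytest.raises(ValueError):
            intensity_ratio_profile(
                make_table([1], [10.0], [0.1]), make_table([2], [10.0], [0.1])
            )

    def test_reciprocal_profiles_multiply_to_one(self):
        a, b = gen_peak_pair(20, 0.7, snr_a=200.0, snr_b=200.0, seed=5)
        ab = intensity_ratio_profile(a, b).set_index("residue_id")
        ba = intensity_ratio_profile(b, a).set_index("residue_id")
        for rid in ab.index:
            if ab.at[rid, "status"] == ba.at[rid, "status"] == "ok":
                assert ab.at[rid, "ratio"] * ba.at[rid, "ratio"] == pytest.approx(1.0)

    def test_attenuated_prm_residues_are_flagged(self):
        # titration fixture: high-affinity proline-rich-motif residues
        # broadened beyond detection, everything else unperturbed
        ids = np.arange(230, 330)
        attenuated = {243, 279, 312}
        ratio = np.where(np.isin(ids, list(attenuated)), 0.01, 1.0)
        ref, perturbed = gen_peak_pair(
            len(ids), ratio, snr_a=50.0, snr_b=50.0, seed=9, residue_ids=ids
        )
        profile = intensity_ratio_profile(perturbed, ref)
        flagged = set(profile.loc[profile.status == "broadened", "residue_id"])
        assert flagged == attenuated


class TestFitExponential:
    def test_noiseless_decay_recovered_exactly(self):
        delays = np.array([0.0, 0.01, 0.02, 0.04, 0.08])
        series = DecaySeries(0, delays, 100.0 * np.exp(-20.0 * delays))
        rate, amplitude, rate_sigma = fit_exponential(series)
        assert rate == pytest.approx(20.0, rel=1e-6)
        assert amplitude == pytest.approx(100.0, rel=1e-6)
        assert rate_sigma == pytest.approx(0.0, abs=1e-3)

    def test_constant_series_raises(self):
        with pytest.raises(FitError):
            fit_exponential(DecaySeries(0, [0.0, 0.01, 0.02], [5.0, 5.0, 5.0]))

    def test_two_points_insufficient(self):
        with pytest.raises(FitError):
            fit_exponential(DecaySeries(0, [0.0, 0.01], [100.0, 80.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.5, 50.0))
    def test_scale_equivariance(self, c):
        delays = np.array([0.0, 0.02, 0.04, 0.06, 0.1])
        y = 80.0 * np.exp(-15.0 * delays)
        r1, a1, _ = fit_exponential(DecaySeries(0, delays, y))
        r2, a2, _ = fit_exponential(DecaySeries(0, delays, c * y))
        assert r2 == pytest.approx(r1, rel=1e-9)
        assert a2 == pytest.approx(c * a1, rel=1e-9)

    def test_noisy_rate_recovery_within_ten_percent(self):
        rates = []
        for seed in range(50):
            series = gen_decay_series(DecayParams(
                amplitude=100.0, rate_per_s=20.0, noise_sd=2.0, seed=seed,
            ))
            rates.append(fit_exponential(series)[0])
        assert abs(np.median(rates) - 20.0) / 20.0 < 0.10


class TestTractEta:
    def test_noiseless_difference(self):
        delays = np.array([0.0, 0.01, 0.02, 0.04, 0.08])
        trosy = DecaySeries(0, delays, 100.0 * np.exp(-10.0 * delays), "trosy")
        anti = DecaySeries(0, delays, 100.0 * np.exp(-30.0 * delays), "anti_trosy")
        r_t, r_a, eta, _ = tract_eta(trosy, anti)
        assert r_t == pytest.approx(10.0, rel=1e-6)
        assert r_a == pytest.approx(30.0, rel=1e-6)
        assert eta == pytest.approx(10.0, rel=1e-6)

    def test_identical_series_give_zero_eta(self):
        delays = np.array([0.0, 0.02, 0.05, 0.09])
        s = DecaySeries(0, delays, 50.0 * np.exp(-12.0 * delays))
        _, _, eta, _ = tract_eta(s, s)
        assert eta == pytest.approx(0.0, abs=1e-9)

    def test_eta_bias_below_combined_sigma_at_snr_50(self):
        etas, sigmas = [], []
        for seed in range(30):
            trosy = gen_decay_series(DecayParams(rate_per_s=10.0, noise_sd=2.0, seed=seed))
            anti = gen_decay_series(DecayParams(rate_per_s=30.0, noise_sd=2.0, seed=seed + 10000))
            trosy.component, anti.component = "trosy", "anti_trosy"
            _, _, eta, sigma = tract_eta(trosy, anti)
            etas.append(eta)
            sigmas.append(sigma)
        bias = abs(np.mean(etas) - 10.0)
        assert bias < np.mean(sigmas)


class TestPreDeltaR2:
    def test_equal_intensities_give_zero(self):
        rec = pre_delta_r2(PRERecord(1, i_para=30.0, i_dia=30.0, delta_t_s=0.007))
        assert rec.gamma2_per_s == pytest.approx(0.0)

    def test_two_fold_attenuation_closed_form(self):
        rec = pre_delta_r2(PRERecord(1, i_para=50.0, i_dia=100.0, delta_t_s=0.007))
        assert rec.gamma2_per_s == pytest.approx(np.log(2.0) / 0.007, abs=1e-6)

    def test_nonpositive_intensity_gives_none_with_reason(self):
        rec = pre_delta_r2(PRERecord(1, i_para=0.0, i_dia=100.0, delta_t_s=0.007))
        assert rec.gamma2_per_s is None
        assert "paramagnetic" in rec.reason

    def test_antisymmetric_under_swapping_para_dia(self):
        fwd = pre_delta_r2(PRERecord(1, i_para=40.0, i_dia=90.0, delta_t_s=0.007))
        rev = pre_delta_r2(PRERecord(1, i_para=90.0, i_dia=40.0, delta_t_s=0.007))
        assert fwd.gamma2_per_s == pytest.approx(-rev.gamma2_per_s)


class TestTableValidation:
    def test_duplicate_residue_ids_rejected(self):
        with pytest.raises(ValueError):
            make_table([1, 1], [10.0, 20.0], [0.1, 0.1])

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            make_table([1], [10.0], [0.0])

    def test_decreasing_delays_rejected(self):
        with pytest.raises(ValueError):
            DecaySeries(0, [0.0, 0.02, 0.01], [3.0, 2.0, 1.0])
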