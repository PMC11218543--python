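"""HRV feature unit and property tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles as orc
from hrvfatigue.containers import InsufficientDataError, InvalidSpecError, RRSeries
from hrvfatigue.hrv import (
    FEATURE_NAMES,
    SpectralEstimate,
    band_powers,
    ccm,
    extract_all,
    poincare,
    porta_index,
    psd_welch,
    time_domain,
    tinn,
    triangle_areas,
    vli,
)
from conftest import random_rr


class TestTimeDomain:
    def test_constant_series(self):
        td = time_domain(RRSeries([1000.0] * 3))
        assert td["meanHR"] == 60.0
        assert td["SDNN"] == td["RMSSD"] == td["PNN50"] == 0.0

    @pytest.mark.parametrize(
        "rr, field, expected",
        [
            ([800, 810, 790, 805], "meanRR", 801.25),
            ([800, 810, 790, 805], "SDNN", 7.39510), # population 1/N form
            ([800, 810, 790], "RMSSD", 15.81139),  # sqrt((10^2 + 20^2)/2)
            ([800, 860, 865, 870], "PNN50", 25.0),  # NN50=1 over N=4
        ],
    )
    def test_printed_formula_examples(self, rr, field, expected):
        assert time_domain(RRSeries(rr))[field] == pytest.approx(expected, abs=1e-4)

    def test_conventional_dialect_uses_sample_forms(self):
        rr = RRSeries([800.0, 860.0, 865.0, 870.0])
        printed = time_domain(rr, dialect="printed")
        conv = time_domain(rr, dialect="conventional")
        assert conv["SDNN"] == pytest.approx(np.std(rr.intervals, ddof=1))
        assert conv["SDNN"] > printed["SDNN"]
        assert conv["PNN50"] == pytest.approx(100.0 / 3.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            time_domain(RRSeries([800.0, 810.0]))


class TestTinn:
    def test_degenerate_single_bin(self):
        val, flag = tinn(RRSeries([800.0] * 30), return_flag=True)
        assert val == 0.0 and flag == "degenerate-histogram"

    def test_exact_symmetric_triangle_recovered(self):
        # counts 1,3,5,7,5,3,1 at consecutive bin centers lie exactly on
        # a triangle with apex at the mode and zeros half a bin beyond
        # the occupied ends, i.e. on bin edges: TINN = 7 bins exactly
        w = 1000.0 / 128.0
        centers = np.arange(100, 107) * w
        counts = [1, 3, 5, 7, 5, 3, 1]
        rr = np.repeat(centers, counts)
        assert tinn(RRSeries(rr)) == pytest.approx(7 * w)  # 54.6875 ms

    def test_uniform_histogram_spans_range(self, rng):
        rr = rng.uniform(750.0, 850.0, size=400)
        assert tinn(RRSeries(rr)) >= 100.0

    def test_matches_joint_brute_force(self, rng):
        for _ in range(10):
            rr = random_rr(rng, 120)
            assert tinn(RRSeries(rr)) == pytest.approx(orc.o_tinn(rr), rel=1e-12)


class TestSpectral:
    def test_constant_rr_has_no_power(self):
        spec = psd_welch(RRSeries([800.0] * 200))
        # total spectral mass of a constant (detrended) tachogram is ~0,
        # which makes the normalized powers undefined
        assert np.trapezoid(spec.psd, spec.freqs) < 1e-12
        with pytest.raises(InvalidSpecError):
            band_powers(spec)

    def test_single_lf_modulation_peaks_in_band(self, rng):
        from hrvfatigue.simulate import ModulationSpec, generate_rr_ipfm

        rr = generate_rr_ipfm(ModulationSpec(amp_vlf=0, amp_lf=0.05, amp_hf=0, seed=2))
        spec = psd_welch(rr)
        peak_f = spec.freqs[np.argmax(spec.psd)]
        assert 0.09 <= peak_f <= 0.11

    def test_parseval_on_resampled_tachogram(self, long_rr):
        spec = psd_welch(long_rr)
        total = np.trapezoid(spec.psd, spec.freqs)
        # compare against the variance of the oracle's resampled series
        freqs, psd = orc.o_welch_psd(long_rr.intervals)
        var = np.var(long_rr.intervals)  # tachogram variance, ms^2
        assert total == pytest.approx(var, rel=0.35)  # windowing loss allowed
        assert total == pytest.approx(np.trapezoid(psd, freqs), rel=1e-9)

    def test_welch_matches_manual_oracle(self, long_rr):
        spec = psd_welch(long_rr)
        freqs, psd = orc.o_welch_psd(long_rr.intervals)
        np.testing.assert_allclose(spec.freqs, freqs, rtol=1e-12)
        np.testing.assert_allclose(spec.psd, psd, rtol=1e-9, atol=1e-12)

    def test_too_short_segment_names_minimum(self):
        with pytest.raises(InsufficientDataError, match="120"):
            psd_welch(RRSeries([800.0] * 20))

    def test_lombscargle_agrees_on_band_fractions(self, ipfm_rr):
        bw = band_powers(psd_welch(ipfm_rr))
        bl = band_powers(psd_welch(ipfm_rr, method="lombscargle"))
        assert bl["LFn"] == pytest.approx(bw["LFn"], abs=8.0)


class TestBandPowers:
    def _flat_spec(self, lf=1.0, hf=1.0, vlf=0.0):
        f = np.arange(0.0, 0.5001, 0.005)
        p = np.zeros_like(f)
        p[(f >= 0.04) & (f < 0.15)] = lf
        p[(f >= 0.15) & (f <= 0.4)] = hf
        p[(f >= 0.003) & (f < 0.04)] = vlf
        return SpectralEstimate(f, p)

    def test_equal_lf_hf_split(self):
        # densities chosen so both bands integrate to the same power
        bp = band_powers(self._flat_spec(lf=1.0 / 0.11, hf=1.0 / 0.25))
        assert bp["HFn"] == pytest.approx(50.0, abs=2.0)
        assert bp["HFn"] + bp["LFn"] == pytest.approx(100.0, abs=1e-9)
        assert bp["LFn_HFn"] == pytest.approx(1.0, abs=0.1)

    def test_all_power_in_lf(self):
        bp = band_powers(self._flat_spec(lf=1.0, hf=0.0))
        assert bp["LFn"] == pytest.approx(100.0)
        assert bp["HFn"] == pytest.approx(0.0)
        assert not np.isfinite(bp["LFn_HFn"])

    def test_grid_must_cover_bands(self):
        f = np.arange(0.05, 0.3, 0.005)
        with pytest.raises(InvalidSpecError):
            band_powers(SpectralEstimate(f, np.ones_like(f)))

    def test_matches_naive_panel_oracle(self, long_rr):
        spec = psd_welch(long_rr)
        mine = band_powers(spec)
        ref = orc.o_band_powers(spec.freqs, spec.psd)
        for k in ("VLF", "LF", "HF", "TP", "HFn", "LFn", "LFn_HFn"):
            assert mine[k] == pytest.approx(ref[k], rel=1e-9)


class TestNonlinear:
    def test_poincare_alternating(self):
        pc = poincare(RRSeries([800.0, 820.0, 800.0, 820.0, 800.0]))
        assert pc["SD1"] == pytest.approx(20.0 / np.sqrt(2.0))
        assert pc["SD2"] == pytest.approx(0.0, abs=1e-9)
        assert pc["S"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(pc["SD1_SD2"])

    def test_constant_series_all_zero(self):
        pc = poincare(RRSeries([900.0] * 10))
        assert pc["SD1"] == pc["SD2"] == pc["S"] == 0.0

    def test_sd1_rmssd_identity_when_diff_mean_zero(self, rng):
        # closing the loop (last == first) forces mean(dRR) = 0
        rr = random_rr(rng, 100)
        rr[-1] = rr[0]
        td = time_domain(RRSeries(rr))
        pc = poincare(RRSeries(rr))
        assert pc["SD1"] == pytest.approx(td["RMSSD"] / np.sqrt(2.0), rel=1e-9)

    def test_vli_equals_sd2(self, long_rr):
        assert vli(long_rr) == poincare(long_rr)["SD2"]

    def test_porta_index_cases(self):
        assert porta_index(RRSeries([800, 810, 820, 830])) == 0.0
        assert porta_index(RRSeries([830, 820, 810, 800])) == 100.0
        assert porta_index(RRSeries([800, 820, 800, 820, 800])) == 50.0
        assert np.isnan(porta_index(RRSeries([800.0, 800.0, 800.0])))

    def test_ccm_single_triangle_area(self):
        areas = triangle_areas(RRSeries([800.0, 810.0, 790.0, 805.0]))
        assert areas.tolist() == [125.0]

    def test_ccm_collinear_points_zero(self):
        # RR_{i+1} = 2 RR_i - 400 puts every Poincare point on one line
        # (slope 2, so SD1 and SD2 both stay positive): zero areas
        assert ccm(RRSeries([800.0, 1200.0, 2000.0, 3600.0, 6800.0])) == pytest.approx(0.0)

    def test_ccm_degenerate_ellipse_raises(self):
        with pytest.raises(InvalidSpecError):
            ccm(RRSeries([800.0, 820.0, 800.0, 820.0, 800.0]))


class TestOracleSweep:
    """Every feature equals its naive-loop oracle on random series."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_series(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(50, 401))
        rr = random_rr(rng, n)
        series = RRSeries(rr)
        td = time_domain(series)
        assert td["meanRR"] == pytest.approx(orc.o_mean_rr(rr), rel=1e-9)
        assert td["meanHR"] == pytest.approx(orc.o_mean_hr(rr), rel=1e-9)
        assert td["SDNN"] == pytest.approx(orc.o_sdnn(rr), rel=1e-9)
        assert td["RMSSD"] == pytest.approx(orc.o_rmssd(rr), rel=1e-9)
        assert td["SDSD"] == pytest.approx(orc.o_sdsd(rr), rel=1e-9)
        assert td["PNN50"] == pytest.approx(orc.o_pnn50(rr), rel=1e-9)
        pc = poincare(series)
        assert pc["SD1"] == pytest.approx(orc.o_sd1(rr), rel=1e-9)
        assert pc["SD2"] == pytest.approx(orc.o_sd2(rr), rel=1e-9)
        assert pc["S"] == pytest.approx(orc.o_s(rr), rel=1e-9)
        assert vli(series) == pytest.approx(orc.o_vli(rr), rel=1e-9)
        assert porta_index(series) == pytest.approx(orc.o_pi(rr), rel=1e-9)
        assert ccm(series) == pytest.approx(orc.o_ccm(rr), rel=1e-9)
        assert tinn(series) == pytest.approx(orc.o_tinn(rr), rel=1e-12)


class TestExtractAll:
    def test_ipfm_fixture_fully_populated(self, ipfm_rr):
        feats = extract_all(ipfm_rr)
        assert feats.n_missing == 0
        assert set(feats.to_dict()) == set(FEATURE_NAMES)
        assert feats["HFn"] + feats["LFn"] == pytest.approx(100.0, abs=1e-9)

    def test_constant_rr_flags_undefined_features(self):
        feats = extract_all(RRSeries([800.0] * 200))
        assert feats["SDNN"] == 0.0 and feats["RMSSD"] == 0.0
        assert np.isnan(feats["CCM_1"]) and "CCM_1" in feats.flags
        assert np.isnan(feats["PI"]) and "PI" in feats.flags
        # constant tachogram: zero spectral mass -> normalization undefined
        assert np.isnan(feats["LFn"]) and "LFn" in feats.flags

    def test_shuffling_preserves_distributional_features(self, long_rr, rng):
        shuffled = RRSeries(rng.permutation(long_rr.intervals))
        a, b = extract_all(long_rr), extract_all(shuffled)
        # PNN50 counts successive differences, so it is order-dependent
        # and excluded from the distributional set
        for k in ("meanRR", "meanHR", "SDNN", "TINN"):
            assert a[k] == pytest.approx(b[k], rel=1e-9)
        assert a["RMSSD"] != pytest.approx(b["RMSSD"], rel=1e-6)
        assert a["CCM_1"] != pytest.approx(b["CCM_1"], rel=1e-6)


@given(
    scale=st.floats(min_value=0.5, max_value=1.8),
    seed=st.integers(min_value=0, max_value=50),
)
def test_scale_equivariance(scale, seed):
    """Multiplying RR by c scales ms features by c, ms^2 by c^2, and
    leaves ratio/percentage features invariant (PNN50's fixed 50 ms
    threshold makes it scale-dependent by design)."""
    rng = np.random.default_rng(seed)
    rr = random_rr(rng, 80)
    a = RRSeries(rr)
    b = RRSeries(rr * scale)
    ta, tb = time_domain(a), time_domain(b)
    for k in ("meanRR", "SDNN", "RMSSD", "SDSD"):
        assert tb[k] == pytest.approx(scale * ta[k], rel=1e-9)
    pa, pb = poincare(a), poincare(b)
    assert pb["S"] == pytest.approx(scale**2 * pa["S"], rel=1e-9)
    assert pb["SD1_SD2"] == pytest.approx(pa["SD1_SD2"], rel=1e-9)
    assert porta_index(b) == pytest.approx(porta_index(a), rel=1e-9)
    assert ccm(b) == pytest.approx(ccm(a), rel=1e-9)
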