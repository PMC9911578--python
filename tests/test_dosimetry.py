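"""Density calibration, S-value scaling, Lea-Catcheside factors, BED chain."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_series
from oracles import lea_catcheside_quadrature
from tacdose.data import TimeActivitySample, VoiSeries
from tacdose.dosimetry import (
    KIDNEY,
    TUMOR,
    DensityCalibration,
    absorbed_dose,
    bed,
    density_from_hu,
    dose_rate_fractions,
    lea_catcheside_bi,
    lea_catcheside_mono,
    scaled_svalue,
    total_tumor_dose,
    voi_dose,
    voi_mass,
)
from tacdose.exceptions import (
    InvalidParameterError,
    MixedPatientError,
    ModelMismatchError,
    NegativeDensityError,
)
from tacdose.fitting import fit_tac
from tacdose.tac_models import ModelId, TacParams


class TestDensityAndMass:
    @pytest.mark.parametrize("hu,expected", [
        (0.0, 0.964),        # calibration intercept
        (-100.0, 0.95606),   # evaluated calibration line
        (1000.0, 1.0434),
    ])
    def test_calibration_line(self, hu, expected):
        assert density_from_hu(hu) == pytest.approx(expected, rel=1e-9)

    def test_negative_density_raises(self):
        with pytest.raises(NegativeDensityError):
            density_from_hu(-1e6)

    def test_voi_mass_mean_of_products(self):
        samples = [TimeActivitySample(19.0, 10.0, 10.0, 0.0),
                   TimeActivitySample(42.0, 9.0, 12.0, 0.0)]
        series = VoiSeries("P", "L", "lesion", samples)
        assert voi_mass(series) == pytest.approx(0.964 * 11.0)  # mean(10, 12) * rho(0)
        assert voi_mass(series, strategy="first") == pytest.approx(9.64)

    def test_unit_density_identity(self):
        cal = DensityCalibration(slope=1e-9, intercept=1.0)
        series = VoiSeries("P", "L", "lesion",
                           [TimeActivitySample(19.0, 1.0, 1.0, 0.0),
                            TimeActivitySample(42.0, 0.5, 1.0, 0.0)])
        assert voi_mass(series, cal) == pytest.approx(1.0, rel=1e-8)


class TestSValueAndDose:
    @pytest.mark.parametrize("tissue,mass,expected", [
        (TUMOR, 1.0, 2.33e-5),      # reference tumour S-value at 1 g
        (KIDNEY, 310.0, 7.38e-8),   # reference kidney S-value at 310 g
        (KIDNEY, 155.0, 1.476e-7),  # inverse-mass scaling
    ])
    def test_inverse_mass_scaling(self, tissue, mass, expected):
        assert scaled_svalue(tissue, mass) == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_mass_raises(self):
        with pytest.raises(InvalidParameterError):
            scaled_svalue(TUMOR, 0.0)

    def test_absorbed_dose_units(self):
        # 10 000 MBq h * 3600 s/h * 4.66e-7 Gy/(MBq s) = 16.776 Gy
        assert absorbed_dose(10_000.0, 4.66e-7) == pytest.approx(16.776)
        assert absorbed_dose(0.0, 4.66e-7) == 0.0
        assert absorbed_dose(10.0, 0.0) == 0.0


class TestLeaCatcheside:
    def test_mono_limits(self):
        assert lea_catcheside_mono(0.01, 0.0) == 1.0
        assert lea_catcheside_mono(0.01, 0.01) == pytest.approx(0.5)

    def test_mono_against_double_integral(self):
        mu = math.log(2) / 1.9
        g = lea_catcheside_mono(0.01, mu)
        assert g == pytest.approx(0.02668, abs=2e-5)
        assert g == pytest.approx(lea_catcheside_quadrature((1.0,), (0.01,), mu), rel=1e-6)

    def test_dose_rate_fractions(self):
        p_bi1 = TacParams(a0=100.0, lambda_bio=0.01, gamma=0.8)
        assert dose_rate_fractions(ModelId.BI1_SHARED_GAMMA, p_bi1) == \
            pytest.approx((0.8, 0.2))
        p_bi2 = TacParams(a0=75.0, lambda_bio=0.01, a1=25.0)
        assert dose_rate_fractions(ModelId.BI2_SHARED_A1, p_bi2) == \
            pytest.approx((0.75, 0.25))
        with pytest.raises(ModelMismatchError):
            dose_rate_fractions(ModelId.MONO, TacParams(a0=1.0, lambda_bio=0.01))

    def test_fractions_normalised(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = TacParams(a0=float(rng.uniform(1, 100)), lambda_bio=0.01,
                          gamma=float(rng.uniform(0.01, 0.99)),
                          a1=float(rng.uniform(0.0, 50.0)))
            for model in (ModelId.BI1_SHARED_GAMMA, ModelId.BI2_SHARED_A1):
                a1, a2 = dose_rate_fractions(model, p)
                assert a1 + a2 == pytest.approx(1.0, rel=1e-14)

    def test_bi_degenerate_reduces_to_mono(self):
        mu = 0.3
        assert lea_catcheside_bi(1.0, 0.0, 0.01, 4.34e-3, mu) == \
            pytest.approx(lea_catcheside_mono(0.01, mu), rel=1e-12)

    def test_bi_equal_rates_collapse(self):
        mu, lam = 0.25, 0.008
        assert lea_catcheside_bi(0.3, 0.7, lam, lam, mu) == \
            pytest.approx(lam / (mu + lam), rel=1e-12)

    def test_bi_against_double_integral_random(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            l1 = 10 ** rng.uniform(-3, -1)
            l2 = 10 ** rng.uniform(-3, -1)
            mu = 10 ** rng.uniform(-1.3, 0)
            a1 = rng.uniform(0.05, 0.95)
            assert lea_catcheside_bi(a1, 1 - a1, l1, l2, mu) == \
                pytest.approx(lea_catcheside_quadrature((a1, 1 - a1), (l1, l2), mu),
                              rel=1e-6)

    def test_monotone_in_repair_and_time_scale(self):
        """More repair during delivery lowers G; uniformly faster delivery
        (both rates scaled up) raises it. Raising one rate alone is NOT
        monotone because it also shifts that component's dose share."""
        mus = np.linspace(0.05, 1.0, 12)
        g_mu = [lea_catcheside_bi(0.7, 0.3, 0.02, 4.34e-3, m) for m in mus]
        assert np.all(np.diff(g_mu) < 0)
        scales = np.linspace(0.5, 8.0, 12)
        g_c = [lea_catcheside_bi(0.7, 0.3, c * 0.02, c * 4.34e-3, 0.3) for c in scales]
        assert np.all(np.diff(g_c) > 0)
        lams = np.linspace(1e-3, 0.1, 12)
        g_l = [lea_catcheside_mono(l, 0.3) for l in lams]
        assert np.all(np.diff(g_l) > 0)


class TestBed:
    def test_zero_dose(self):
        re, b = bed(0.0, 0.5, TUMOR)
        assert re == 1.0 and b == 0.0

    def test_small_g_limit(self):
        _, b = bed(10.0, 1e-12, TUMOR)
        assert b == pytest.approx(10.0, rel=1e-9)

    def test_worked_chain(self):
        """TIA 10 000 MBq h, 50 g lesion, lambda_eff 0.01/h -> BED ≈ 19.20 Gy."""
        s = scaled_svalue(TUMOR, 50.0)
        d = absorbed_dose(10_000.0, s)
        g = lea_catcheside_mono(0.01, TUMOR.mu_per_h)
        _, b = bed(d, g, TUMOR)
        assert d == pytest.approx(16.776)
        assert b == pytest.approx(19.20, abs=0.01)


class TestVoiDose:
    def test_full_chain_matches_worked_example(self):
        params = TacParams(a0=100.0, lambda_bio=5.66e-3)
        # volume/HU chosen so the VOI mass is exactly 50 g
        series = make_series(params, volume_ml=50.0 / 0.964, mean_HU=0.0)
        res = voi_dose(series, fit_tac(ModelId.MONO, series), TUMOR)
        assert res.mass_g == pytest.approx(50.0, rel=1e-9)
        assert res.D_Gy == pytest.approx(16.776, rel=1e-5)
        assert res.BED_Gy == pytest.approx(19.20, abs=0.01)
        assert res.RE >= 1.0 and 0 < res.G <= 1.0

    def test_gamma_one_boundary_equals_mono(self):
        p_bi = TacParams(a0=60.0, lambda_bio=0.015, gamma=1.0)
        p_mono = TacParams(a0=60.0, lambda_bio=0.015)
        series = make_series(p_mono)
        mono = voi_dose(series, fit_tac(ModelId.MONO, series), TUMOR)
        series_bi = make_series(p_bi, ModelId.BI1_SHARED_GAMMA)
        bi = voi_dose(series_bi, fit_tac(ModelId.BI1_SHARED_GAMMA, series_bi,
                                         {"gamma": 1.0 - 1e-12}), TUMOR)
        assert bi.BED_Gy == pytest.approx(mono.BED_Gy, rel=1e-6)

    def test_doubling_mass_halves_dose_and_shrinks_re(self):
        params = TacParams(a0=100.0, lambda_bio=5.66e-3)
        small = make_series(params, volume_ml=20.0, mean_HU=0.0)
        big = make_series(params, volume_ml=40.0, mean_HU=0.0)
        d1 = voi_dose(small, fit_tac(ModelId.MONO, small), TUMOR)
        d2 = voi_dose(big, fit_tac(ModelId.MONO, big), TUMOR)
        assert d2.D_Gy == pytest.approx(d1.D_Gy / 2.0, rel=1e-9)
        assert (d2.BED_Gy - d2.D_Gy) < 0.5 * (d1.BED_Gy - d1.D_Gy)

    def test_activity_scaling_homogeneity(self):
        """Scaling all activities by c scales D by c and BED superlinearly."""
        base = TacParams(a0=50.0, lambda_bio=0.01)
        scaled = TacParams(a0=150.0, lambda_bio=0.01)
        s1 = make_series(base)
        s2 = make_series(scaled)
        d1 = voi_dose(s1, fit_tac(ModelId.MONO, s1), TUMOR)
        d2 = voi_dose(s2, fit_tac(ModelId.MONO, s2), TUMOR)
        assert d2.D_Gy == pytest.approx(3.0 * d1.D_Gy, rel=1e-6)
        assert d2.BED_Gy > 3.0 * d1.BED_Gy
        assert d2.RE > d1.RE


class TestTotalTumorDose:
    def test_single_lesion_identity(self):
        params = TacParams(a0=80.0, lambda_bio=0.012)
        series = make_series(params, volume_ml=30.0)
        fit = fit_tac(ModelId.MONO, series)
        single = voi_dose(series, fit, TUMOR)
        total = total_tumor_dose([(series, fit)])
        assert total.BED_Gy == pytest.approx(single.BED_Gy, rel=1e-9)
        assert total.mass_g == pytest.approx(single.mass_g, rel=1e-12)

    def test_two_identical_lesions_same_bed(self):
        params = TacParams(a0=80.0, lambda_bio=0.012)
        a = make_series(params, volume_ml=30.0, voi_id="L1")
        b = make_series(params, volume_ml=30.0, voi_id="L2")
        fits = [(s, fit_tac(ModelId.MONO, s)) for s in (a, b)]
        total = total_tumor_dose(fits)
        single = voi_dose(a, fits[0][1], TUMOR)
        assert total.mass_g == pytest.approx(2 * single.mass_g, rel=1e-12)
        assert total.BED_Gy == pytest.approx(single.BED_Gy, rel=1e-9)

    def test_mixed_patients_raise(self):
        params = TacParams(a0=80.0, lambda_bio=0.012)
        a = make_series(params, patient_id="P01")
        b = make_series(params, patient_id="P02")
        fits = [(s, fit_tac(ModelId.MONO, s)) for s in (a, b)]
        with pytest.raises(MixedPatientError):
            total_tumor_dose(fits)

    def test_pooled_dose_vs_direct_chain(self):
        """Three heterogeneous lesions: pooled BED equals the analytic chain
        applied to the refit pooled concentration curve."""
        rng = np.random.default_rng(8)
        lesions = []
        for i in range(3):
            params = TacParams(a0=float(rng.uniform(20, 90)),
                               lambda_bio=float(rng.uniform(0.004, 0.02)))
            s = make_series(params, volume_ml=float(rng.uniform(10, 60)),
                            voi_id=f"L{i}")
            lesions.append((s, fit_tac(ModelId.MONO, s)))
        total = total_tumor_dose(lesions)
        assert total.D_Gy > 0 and total.BED_Gy >= total.D_Gy
        # mass additivity
        assert total.mass_g == pytest.approx(sum(voi_mass(s) for s, _ in lesions))


@given(d=st.floats(0.0, 200.0), g=st.floats(1e-6, 1.0))
def test_bed_never_below_absorbed_dose(d, g):
    """BED >= D, strictly whenever G*D is numerically non-zero."""
    _, b = bed(d, g, KIDNEY)
    assert b >= d
    if d * g > 1e-6:
        assert b > d
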