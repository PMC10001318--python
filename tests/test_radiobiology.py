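"""RBE weighting, prescription calibration, radiosensitivity and LQ survival."""

import math

import numpy as np
import pytest

from bnctsim import (
    BioDoseField,
    ConfigurationError,
    DoseComponents,
    RBEWeights,
    build_grid,
    build_oer_field,
    calibrate_prescription,
    generate_ebrt_field,
    make_roi_masks,
    mep_circular,
    sample_radiosensitivity,
    survival_bnct,
    survival_ebrt,
)
from bnctsim.mep import MEPField
from bnctsim.radiobiology import RadiosensitivityField


def _components(alpha, li7, gamma, neutron):
    one = np.ones((1, 1))
    return DoseComponents(
        alpha=alpha * one, li7=li7 * one, gamma=gamma * one, neutron_residual=neutron * one
    )


def _uniform_rs(shape, alpha, beta):
    return RadiosensitivityField(alpha=np.full(shape, alpha), beta=np.full(shape, beta))


class TestWeighting:
    def test_hand_arithmetic_single_cell(self):
        from bnctsim import weight_components

        comp = _components(0.5, 0.3, 0.2, 0.1)
        weights = RBEWeights(w_boron=3.8, w_gamma=1.0, w_neutron=3.2)
        bio = weight_components(comp, weights)
        # 3.8*(0.5+0.3) + 1.0*0.2 + 3.2*0.1 computed by hand
        assert bio.values[0, 0] == pytest.approx(3.56, abs=1e-12)

    def test_identity_weights_give_plain_sum(self):
        from bnctsim import weight_components

        comp = _components(0.5, 0.3, 0.2, 0.1)
        bio = weight_components(comp, RBEWeights(1.0, 1.0, 1.0))
        assert bio.values[0, 0] == pytest.approx(1.1)

    def test_zero_components_give_zero_dose(self):
        from bnctsim import weight_components

        bio = weight_components(_components(0, 0, 0, 0))
        assert bio.values[0, 0] == 0.0

    def test_non_positive_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            RBEWeights(w_boron=0.0)


class TestCalibration:
    def test_field_already_at_prescription(self):
        bio = BioDoseField(values=np.array([[73.4, 10.0]]))
        mask = np.array([[True, True]])
        s, scaled = calibrate_prescription(bio, mask)
        assert s == pytest.approx(1.0)
        np.testing.assert_array_equal(scaled.values, bio.values)

    def test_half_prescription_scales_by_two(self):
        bio = BioDoseField(values=np.array([[36.7, 5.0]]))
        mask = np.array([[True, False]])
        s, scaled = calibrate_prescription(bio, mask)
        assert s == pytest.approx(2.0)
        assert scaled.values[0, 0] == pytest.approx(73.4)

    def test_idempotent(self):
        bio = BioDoseField(values=np.array([[12.0, 3.0]]))
        mask = np.ones((1, 2), bool)
        _, once = calibrate_prescription(bio, mask)
        s2, _ = calibrate_prescription(once, mask)
        assert s2 == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        bio = BioDoseField(values=np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            calibrate_prescription(bio, np.zeros((2, 2), bool))
        with pytest.raises(ConfigurationError):
            calibrate_prescription(bio, np.ones((2, 2), bool))


class TestRadiosensitivitySampling:
    def test_zero_sd_reduces_to_homogeneous(self):
        grid = build_grid(10, 10, 200.0)
        rs = sample_radiosensitivity(grid, alpha_sd=0.0, beta_sd=0.0, seed=1)
        assert np.all(rs.alpha == 0.25) and np.all(rs.beta == 0.025)

    def test_sample_mean_obeys_law_of_large_numbers(self):
        from scipy.stats import truncnorm

        grid = build_grid(1000, 1000, 20.0)
        rs = sample_radiosensitivity(
            grid, alpha_mean=0.25, alpha_sd=0.10, beta_mean=0.025, beta_sd=0.010, seed=2
        )
        # independent closed-form reference: mean of N(0.25, 0.1) truncated at 0
        expected = truncnorm.mean(-2.5, np.inf, loc=0.25, scale=0.10)
        se = 0.10 / math.sqrt(grid.n_cells)
        assert abs(rs.alpha.mean() - expected) < 3 * se
        assert rs.alpha.min() > 0.0 and rs.beta.min() >= 0.0

    def test_heavy_truncation_keeps_positivity(self):
        grid = build_grid(200, 200, 200.0)
        rs = sample_radiosensitivity(
            grid, alpha_mean=0.05, alpha_sd=0.2, beta_mean=0.01, beta_sd=0.05, seed=3
        )
        assert rs.alpha.min() > 0.0
        assert rs.beta.min() >= 0.0

    def test_deterministic_given_seed(self):
        grid = build_grid(30, 30, 200.0)
        a = sample_radiosensitivity(grid, seed=7)
        b = sample_radiosensitivity(grid, seed=7)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)


class TestOERField:
    def test_bnct_mode_is_unity_everywhere(self):
        grid = build_grid(50, 50, 1000.0)
        oer = build_oer_field(grid, mode="bnct", oer_max=3.0)
        assert np.all(oer.values == 1.0)

    def test_ebrt_unity_when_oer_max_is_one(self):
        grid = build_grid(50, 50, 1000.0)
        oer = build_oer_field(grid, mode="ebrt", oer_max=1.0)
        np.testing.assert_allclose(oer.values, 1.0)

    def test_ebrt_monotone_non_increasing_along_ray(self):
        grid = build_grid(51, 51, 1000.0)
        oer = build_oer_field(grid, mode="ebrt", oer_max=3.0, core_radius_mm=2.0)
        ic = 25
        ray = oer.values[ic, ic:]
        assert np.all(np.diff(ray) <= 1e-15)
        assert oer.values[ic, ic] == pytest.approx(3.0)

    def test_invalid_oer_max_rejected(self):
        grid = build_grid(5, 5, 1000.0)
        with pytest.raises(ConfigurationError):
            build_oer_field(grid, mode="ebrt", oer_max=0.5)


class TestSurvival:
    def test_zero_dose_returns_mep(self):
        grid = build_grid(41, 41, 1000.0)
        mep = mep_circular(grid, me_extent_mm=15.0)
        bio = BioDoseField(values=np.zeros(grid.shape))
        rs = _uniform_rs(grid.shape, 0.3, 0.03)
        sp = survival_bnct(mep, bio, rs)
        np.testing.assert_array_equal(sp.values, mep.values)

    def test_zero_mep_kills_everything(self):
        mep = MEPField(values=np.zeros((3, 3)), model_tag="test")
        bio = BioDoseField(values=np.full((3, 3), 5.0))
        sp = survival_bnct(mep, bio, _uniform_rs((3, 3), 0.3, 0.03))
        assert np.all(sp.values == 0.0)

    def test_scalar_lq_evaluation(self):
        mep = MEPField(values=np.ones((1, 1)), model_tag="test")
        bio = BioDoseField(values=np.full((1, 1), 2.0))
        sp = survival_bnct(mep, bio, _uniform_rs((1, 1), 0.3, 0.03))
        # exp(-(0.3*2 + 0.03*4)) = exp(-0.72)
        assert sp.values[0, 0] == pytest.approx(math.exp(-0.72), rel=1e-12)

    def test_survival_bounded_by_mep(self):
        grid = build_grid(61, 61, 1000.0)
        mep = mep_circular(grid, me_extent_mm=25.0)
        rng = np.random.default_rng(0)
        bio = BioDoseField(values=rng.uniform(0, 70, grid.shape))
        rs = sample_radiosensitivity(grid, seed=4)
        sp = survival_bnct(mep, bio, rs)
        assert np.all(sp.values <= mep.values + 1e-15)
        assert np.all(sp.values >= 0.0)

    def test_negative_dose_rejected(self):
        mep = MEPField(values=np.ones((1, 1)), model_tag="test")
        bio = BioDoseField(values=np.array([[-1.0]]))
        with pytest.raises(ConfigurationError):
            survival_bnct(mep, bio, _uniform_rs((1, 1), 0.3, 0.03))


class TestSurvivalEBRT:
    def _setup(self, grid, oer_max=1.0):
        masks = make_roi_masks(grid, beam_radius_mm=25.0)
        mep = mep_circular(grid)
        rs = _uniform_rs(grid.shape, 0.3, 0.03)
        oer = build_oer_field(grid, mode="ebrt", oer_max=oer_max)
        return masks, mep, rs, oer

    def test_single_fraction_reduces_to_bnct_form(self):
        grid = build_grid(91, 91, 1000.0)
        masks, mep, rs, oer = self._setup(grid, oer_max=1.0)
        field = generate_ebrt_field(
            grid, masks.gtv, 25.0, fraction_dose_gy=2.0, n_fractions=1,
            boost_gy=0.0, noise_rel=0.0,
        )
        sp_frac = survival_ebrt(mep, field, rs, oer)
        sp_single = survival_bnct(mep, BioDoseField(values=field.fraction_dose), rs)
        np.testing.assert_allclose(sp_frac.values, sp_single.values, rtol=1e-12)

    def test_thirty_fraction_scalar_value(self):
        grid = build_grid(5, 5, 1000.0)
        rs = _uniform_rs(grid.shape, 0.3, 0.03)
        oer = build_oer_field(grid, mode="ebrt", oer_max=1.0)
        mep = MEPField(values=np.ones(grid.shape), model_tag="test")
        field = generate_ebrt_field(
            grid, np.zeros(grid.shape, bool), 1000.0, fraction_dose_gy=2.0,
            n_fractions=30, boost_gy=0.0, noise_rel=0.0,
        )
        sp = survival_ebrt(mep, field, rs, oer)
        # 30 identical 2 Gy fractions: exp(-30*0.72) at the centre
        assert sp.values[2, 2] == pytest.approx(math.exp(-21.6), rel=1e-6)

    def test_hypoxia_strictly_increases_survival(self):
        grid = build_grid(91, 91, 1000.0)
        masks, mep, rs, _ = self._setup(grid)
        field = generate_ebrt_field(grid, masks.gtv, 25.0, noise_rel=0.0)
        sp_oxic = survival_ebrt(mep, field, rs, build_oer_field(grid, "ebrt", oer_max=1.0))
        sp_hypoxic = survival_ebrt(mep, field, rs, build_oer_field(grid, "ebrt", oer_max=2.0))
        centre = (45, 45)
        assert sp_hypoxic.values[centre] > sp_oxic.values[centre]
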