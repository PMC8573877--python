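import numpy as np
import pytest

from psirsynth import (
    MSashaModel,
    TissueReference,
    TissueRelaxation,
    calc_bb_psir,
    calc_db_psir,
    compute_a_db,
    db_attenuation_curve,
    estimate_normal_values,
    lgeb_sweep,
    make_cardiac_phantom,
    simulate_series,
    default_msasha_protocol,
)


def a_db_oracle(t1m, t2m, t1b, t2b, lgeb):
    """Independent hand evaluation of the blood-anchoring solution."""
    r1m, r2m, r1b, r2b = 1000 / t1m, 1000 / t2m, 1000 / t1b, 1000 / t2b
    return (r1m * r2m / (r1b - lgeb) - r2m) / (r2b - r2m)


class TestADb:
    def test_chronic_group_means(self, chronic_reference):
        expected = a_db_oracle(668.0, 42.4, 466.0, 142.4, -0.5)
        assert compute_a_db(chronic_reference) == pytest.approx(expected, rel=1e-12)
        assert compute_a_db(chronic_reference) == pytest.approx(0.618, abs=0.001)

    def test_unity_fixed_point(self):
        # choose LGEb so that R1m R2m / (R1b - LGEb) = R2b, forcing a_DB = 1
        r1m, r2m, r1b, r2b = 1.5, 23.0, 2.1, 7.0
        lgeb = r1b - r1m * r2m / r2b
        ref = TissueReference(r1m, r2m, r1b, r2b, lgeb=lgeb)
        assert ref.a_db == pytest.approx(1.0, rel=1e-12)

    def test_equal_blood_and_myocardium_r2_rejected(self):
        with pytest.raises(ValueError, match="r2b"):
            TissueReference(1.5, 23.0, 2.1, 23.0)

    def test_lgeb_equal_to_blood_r1_rejected(self):
        with pytest.raises(ValueError, match="lgeb"):
            TissueReference(1.5, 23.0, 2.1, 7.0, lgeb=2.1)

    def test_a_db_tracks_field_changes(self, chronic_reference):
        assert chronic_reference.with_lgeb(0.0).a_db != chronic_reference.a_db


class TestBrightBlood:
    def test_null_at_normal_myocardium(self, chronic_reference):
        img = calc_bb_psir(np.array([[chronic_reference.r1m]]), chronic_reference)
        assert img.values[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_chronic_mi_signal(self, chronic_reference):
        img = calc_bb_psir(np.array(1000.0 / 441.0), chronic_reference)
        # direct subtraction of the printed-derived rates
        assert img.values == pytest.approx(1000 / 441 - 1000 / 668, rel=1e-12)
        assert img.values == pytest.approx(0.77, abs=0.005)

    def test_linear_in_rate_offset(self, chronic_reference):
        r1 = chronic_reference.r1m
        one = calc_bb_psir(np.array(r1 + 0.3), chronic_reference).values
        two = calc_bb_psir(np.array(r1 + 0.6), chronic_reference).values
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nan_propagates(self, chronic_reference):
        img = calc_bb_psir(np.array([np.nan, 2.0]), chronic_reference)
        assert np.isnan(img.values[0]) and np.isfinite(img.values[1])


class TestDarkBlood:
    def test_equals_bright_blood_at_normal_r2(self, chronic_reference):
        r1 = np.linspace(1.0, 3.0, 7)
        r2 = np.full_like(r1, chronic_reference.r2m)
        db = calc_db_psir(r1, r2, chronic_reference).values
        bb = calc_bb_psir(r1, chronic_reference).values
        np.testing.assert_allclose(db, bb, rtol=1e-12)

    def test_blood_lands_at_lgeb(self, chronic_reference):
        db = calc_db_psir(
            np.array(chronic_reference.r1b), np.array(chronic_reference.r2b), chronic_reference
        )
        assert db.values == pytest.approx(-0.5, abs=1e-9)

    def test_chronic_mi_signal(self, chronic_reference):
        db = calc_db_psir(np.array(1000 / 441.0), np.array(1000 / 43.8), chronic_reference)
        # hand-evaluated formula with the oracle a_DB
        a = a_db_oracle(668.0, 42.4, 466.0, 142.4, -0.5)
        denom = a * (1000 / 43.8) / (1000 / 42.4) + (1 - a)
        expected = 1000 / 441 - (1000 / 668) / denom
        assert db.values == pytest.approx(expected, rel=1e-12)
        assert db.values == pytest.approx(0.74, abs=0.005)

    def test_nonpositive_denominator_counted_as_nan(self, chronic_reference):
        # LGEb close to R1b pushes a_DB far negative, so a short-T2 pixel
        # drives the denominator below zero
        ref = chronic_reference.with_lgeb(2.0)
        assert ref.a_db < 0
        with pytest.warns(UserWarning, match="denominator"):
            img = calc_db_psir(np.array([2.0]), np.array([30.0]), ref)
        assert img.n_invalid == 1
        assert np.isnan(img.values[0])

    def test_shape_mismatch_rejected(self, chronic_reference):
        with pytest.raises(ValueError, match="shape"):
            calc_db_psir(np.ones((2, 2)), np.ones(3), chronic_reference)


@pytest.fixture(scope="module")
def fitted_chronic():
    ph = make_cardiac_phantom("chronic_mi", shape=(64, 64), r_blood=14, r_epi=20)
    series = simulate_series(ph, default_msasha_protocol(), snr=np.inf)
    res = MSashaModel(series).fit(mask=ph.label_map > 0)
    return ph, res


class TestNormalValueEstimation:
    def test_median_dominated_by_remote(self, fitted_chronic):
        ph, res = fitted_chronic
        myo = ph.mask(["remote", "mi"])
        assert ph.mask("mi").sum() < 0.5 * myo.sum()
        t1m, t2m = estimate_normal_values(res, myo)
        assert t1m == pytest.approx(668.0, rel=0.01)
        assert t2m == pytest.approx(42.4, rel=0.01)

    def test_uniform_region_gives_exact_value(self, fitted_chronic):
        ph, res = fitted_chronic
        t1b, t2b = estimate_normal_values(res, ph.mask("blood"))
        assert t1b == pytest.approx(466.0, rel=1e-3)
        assert t2b == pytest.approx(142.4, rel=1e-3)

    def test_single_pixel_mask(self, fitted_chronic):
        ph, res = fitted_chronic
        px = np.argwhere(ph.mask("remote") & res.converged_mask)[0]
        mask = np.zeros(ph.shape, dtype=bool)
        mask[tuple(px)] = True
        t1, t2 = estimate_normal_values(res, mask)
        assert t1 == res.t1_map[tuple(px)]

    def test_empty_mask_rejected(self, fitted_chronic):
        _, res = fitted_chronic
        with pytest.raises(ValueError, match="empty"):
            estimate_normal_values(res, np.zeros(res.t1_map.shape, dtype=bool))


@pytest.fixture(scope="module")
def rate_maps():
    # noise-free rate vectors of the three chronic tissues (MI, remote, blood)
    t1 = np.array([441.0, 668.0, 466.0])
    t2 = np.array([43.8, 42.4, 142.4])
    return 1000.0 / t1, 1000.0 / t2


class TestLgebSweep:
    def test_default_endpoint_matches_calc_db(self, rate_maps, chronic_reference):
        r1, r2 = rate_maps
        sweep = lgeb_sweep(r1, r2, chronic_reference, [-0.5])
        direct = calc_db_psir(r1, r2, chronic_reference)
        np.testing.assert_array_equal(sweep[0].values, direct.values)

    def test_blood_anchored_at_every_lgeb(self, rate_maps, chronic_reference):
        r1, r2 = rate_maps
        lgebs = [1.0, 0.5, 0.0, -0.25, -0.5, -1.0]
        for img, lgeb in zip(lgeb_sweep(r1, r2, chronic_reference, lgebs), lgebs):
            assert img.values[2] == pytest.approx(lgeb, abs=1e-9)

    def test_blood_signal_monotone_in_lgeb(self, rate_maps, chronic_reference):
        r1, r2 = rate_maps
        lgebs = np.linspace(1.0, -1.0, 9)
        blood = [img.values[2] for img in lgeb_sweep(r1, r2, chronic_reference, lgebs)]
        assert np.all(np.diff(blood) < 0)

    def test_unity_a_db_edge_case_handled(self, chronic_reference):
        lgeb = chronic_reference.r1b - chronic_reference.r1m * chronic_reference.r2m / chronic_reference.r2b
        img = lgeb_sweep(
            np.array([chronic_reference.r1b]),
            np.array([chronic_reference.r2b]),
            chronic_reference,
            [lgeb],
        )[0]
        assert img.reference.a_db == pytest.approx(1.0, rel=1e-12)
        assert img.values[0] == pytest.approx(lgeb, abs=1e-9)


class TestAttenuationCurve:
    REMOTE = TissueRelaxation(600.0, 42.0)
    BLOOD = TissueRelaxation(400.0, 150.0)

    def test_unity_at_remote_t2(self):
        t1g = np.array([300.0, 450.0, 550.0])
        att = db_attenuation_curve(t1g, np.array([42.0]), self.REMOTE, self.BLOOD)
        np.testing.assert_allclose(att[:, 0], 1.0, rtol=1e-12)

    def test_strictly_decreasing_in_t2(self):
        t1g = np.array([300.0, 400.0, 500.0])
        t2g = np.linspace(42.0, 100.0, 40)
        ref = type(self).REMOTE
        att = db_attenuation_curve(t1g, t2g, self.REMOTE, self.BLOOD)
        assert np.all(np.diff(att, axis=1) < 0)

    def test_finite_over_stated_grid(self):
        t1g = np.linspace(300.0, 550.0, 6)
        t2g = np.linspace(42.0, 100.0, 30)
        att = db_attenuation_curve(t1g, t2g, self.REMOTE, self.BLOOD, lgeb=-0.5)
        assert att.shape == (6, 30)
        assert np.isfinite(att).all()

    def test_nan_where_bb_signal_vanishes(self):
        att = db_attenuation_curve(
            np.array([600.0]), np.array([60.0]), self.REMOTE, self.BLOOD
        )
        assert np.isnan(att[0, 0])

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            db_attenuation_curve([-300.0], [60.0], self.REMOTE, self.BLOOD)
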