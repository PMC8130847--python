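"""Degradation law: evaluation, inversion, accumulation, fitting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from scaffold_degrade import kinetics
from scaffold_degrade.kinetics import (
    DegradationCoefficients,
    DegradationRecord,
    advance_damage,
    degradation_degree,
    fit_coefficients,
    fracture_strain,
    fracture_time,
)
from scaffold_degrade.synthetic import COUPON_DESIGN, generate_degradation_dataset


def bisect_fracture_time(strain: float, coeffs: DegradationCoefficients) -> float:
    """Independent oracle: bisection on D(eps, t) = 1 - eps/eps0."""
    target = 1.0 - strain / coeffs.epsilon0
    return brentq(
        lambda t: degradation_degree(strain, t, coeffs) - target,
        1e-9, 1e6, xtol=1e-9,
    )


class TestDegradationDegree:
    @pytest.mark.parametrize(
        "strain, t, expected",
        [
            (0.4, 0.0, 0.0),  # no time, no degradation
            (0.4, 30.0, 0.7986435061685861),  # hand evaluation of the power law
            (0.0, 30.0, 0.18727499173114115),  # strain term vanishes, a*b*t^m
        ],
    )
    def test_known_values(self, coeffs, strain, t, expected):
        assert degradation_degree(strain, t, coeffs) == pytest.approx(expected, rel=1e-12)

    def test_capped_at_one(self, coeffs):
        assert degradation_degree(0.4, 1e5, coeffs) == 1.0

    @pytest.mark.parametrize("kwargs", [dict(strain=-0.1, time_days=1.0),
                                        dict(strain=0.1, time_days=-1.0)])
    def test_negative_inputs_rejected(self, coeffs, kwargs):
        with pytest.raises(ValueError, match="strain|time_days"):
            degradation_degree(kwargs["strain"], kwargs["time_days"], coeffs)

    def test_monotone_in_strain_and_time(self, coeffs):
        eps = np.linspace(0, 1, 41)
        t = np.linspace(0, 400, 81)
        d = degradation_degree(eps[:, None], t[None, :], coeffs)
        assert np.all(np.diff(d, axis=0) >= 0)
        assert np.all(np.diff(d, axis=1) >= 0)
        assert np.all((d >= 0) & (d <= 1))


class TestFractureStrain:
    def test_endpoints(self, coeffs):
        assert fracture_strain(0.0, coeffs) == pytest.approx(1.22)
        assert fracture_strain(1.0, coeffs) == 0.0
        assert fracture_strain(0.5, coeffs) == pytest.approx(0.61)

    def test_strictly_decreasing(self, coeffs):
        d = np.linspace(0, 1, 101)
        assert np.all(np.diff(fracture_strain(d, coeffs)) < 0)

    @pytest.mark.parametrize("degree", [-0.01, 1.01])
    def test_domain(self, coeffs, degree):
        with pytest.raises(ValueError, match="degree"):
            fracture_strain(degree, coeffs)


class TestFractureTime:
    def test_published_bounds(self, coeffs):
        # >0.3 strain fractures within a month; 0.02 survives beyond 7 months
        assert fracture_time(0.3, coeffs) == pytest.approx(29.49, abs=0.01)
        assert fracture_time(0.3, coeffs) <= 30.0
        assert fracture_time(0.02, coeffs) == pytest.approx(231.86, abs=0.01)
        assert fracture_time(0.02, coeffs) >= 7 * 30.0

    def test_at_or_above_initial_fracture_strain(self, coeffs):
        assert fracture_time(coeffs.epsilon0, coeffs) == 0.0
        assert fracture_time(2.0, coeffs) == 0.0

    def test_matches_bisection_oracle(self, coeffs):
        for eps in np.linspace(0.01, 0.5, 9):
            assert fracture_time(eps, coeffs) == pytest.approx(
                bisect_fracture_time(eps, coeffs), abs=1e-6
            )

    def test_strictly_decreasing(self, coeffs):
        eps = np.linspace(0.001, coeffs.epsilon0 * 0.999, 200)
        assert np.all(np.diff(fracture_time(eps, coeffs)) < 0)

    @given(st.floats(0.001, 1.2))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, eps):
        # degrade exactly until fracture: remaining fracture strain == carried strain
        coeffs = DegradationCoefficients()
        t_star = fracture_time(eps, coeffs)
        d = degradation_degree(eps, t_star, coeffs)
        assert fracture_strain(d, coeffs) == pytest.approx(eps, abs=1e-9)

    def test_negative_strain_rejected(self, coeffs):
        with pytest.raises(ValueError, match="strain"):
            fracture_time(-0.1, coeffs)


class TestAdvanceDamage:
    def test_single_step_from_zero_equals_closed_form(self, coeffs):
        assert advance_damage(0.0, 0.4, 30.0, coeffs) == pytest.approx(
            degradation_degree(0.4, 30.0, coeffs), rel=1e-12
        )

    def test_many_small_steps_compose_to_closed_form(self, coeffs):
        d = 0.0
        for _ in range(60):
            d = advance_damage(d, 0.4, 0.5, coeffs)
        assert d == pytest.approx(degradation_degree(0.4, 30.0, coeffs), rel=1e-9)

    @given(st.lists(st.floats(0.01, 20.0), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_partition_invariance(self, dts):
        # any partition of [0, T] at constant strain reproduces the closed form
        coeffs = DegradationCoefficients()
        d = 0.0
        for dt in dts:
            d = advance_damage(d, 0.25, dt, coeffs)
        assert d == pytest.approx(
            degradation_degree(0.25, sum(dts), coeffs), rel=1e-9, abs=1e-12
        )

    def test_saturated_damage_is_absorbing(self, coeffs):
        assert advance_damage(1.0, 0.4, 5.0, coeffs) == 1.0
        assert advance_damage(1.0, 0.0, 1e4, coeffs) == 1.0

    def test_irreversible_when_strain_drops(self, coeffs):
        d = advance_damage(0.0, 0.4, 10.0, coeffs)
        assert advance_damage(d, 0.0, 0.001, coeffs) >= d

    def test_global_time_mode(self, coeffs):
        d = advance_damage(0.3, 0.2, 1.0, coeffs, mode="global_time", elapsed_days=50.0)
        assert d == pytest.approx(degradation_degree(0.2, 50.0, coeffs))
        with pytest.raises(ValueError, match="elapsed_days"):
            advance_damage(0.3, 0.2, 1.0, coeffs, mode="global_time")

    def test_bad_inputs(self, coeffs):
        with pytest.raises(ValueError, match="dt"):
            advance_damage(0.0, 0.4, 0.0, coeffs)
        with pytest.raises(ValueError, match="current_degree"):
            advance_damage(1.5, 0.4, 1.0, coeffs)
        with pytest.raises(ValueError, match="mode"):
            advance_damage(0.0, 0.4, 1.0, coeffs, mode="bogus")


class TestCoefficients:
    @pytest.mark.parametrize(
        "bad", [dict(a=-1.0), dict(b=-0.1), dict(m=0.0), dict(n=-0.2), dict(epsilon0=0.0)]
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            DegradationCoefficients(**bad)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="degree"):
            DegradationRecord(0.2, 10.0, 1.5)
        with pytest.raises(ValueError, match="strain"):
            DegradationRecord(-0.2, 10.0, 0.5)


class TestFitCoefficients:
    def test_noise_free_recovery(self, coeffs):
        records = generate_degradation_dataset(coeffs, COUPON_DESIGN, noise_sd=0.0)
        result = fit_coefficients(records)
        assert result.residual_norm < 1e-8
        np.testing.assert_allclose(
            result.coefficients.as_array(), coeffs.as_array(), rtol=1e-3
        )

    def test_identifiable_products_recovered_from_off_init(self, coeffs):
        # a, b, c are only identifiable through the products ab and ac;
        # from a distant start the fit must still recover those and m, n
        records = generate_degradation_dataset(coeffs, COUPON_DESIGN, noise_sd=0.0)
        init = replace(coeffs, a=0.5, b=0.1, c=0.5, m=0.5, n=0.5)
        c = fit_coefficients(records, init=init).coefficients
        assert c.a * c.b == pytest.approx(coeffs.a * coeffs.b, rel=1e-4)
        assert c.a * c.c == pytest.approx(coeffs.a * coeffs.c, rel=1e-4)
        assert c.m == pytest.approx(coeffs.m, rel=1e-4)
        assert c.n == pytest.approx(coeffs.n, rel=1e-4)

    def test_uniform_noise_recovery(self, coeffs):
        # +/-0.01 uniform measurement noise, fixed seed
        rng = np.random.default_rng(1)
        records = [
            DegradationRecord(
                eps, t,
                float(np.clip(degradation_degree(eps, t, coeffs)
                              + rng.uniform(-0.01, 0.01), 0, 1)),
            )
            for eps in COUPON_DESIGN["strains"]
            for t in COUPON_DESIGN["times"]
        ]
        result = fit_coefficients(records)
        assert result.residual_norm > 0
        np.testing.assert_allclose(
            result.coefficients.as_array(), coeffs.as_array(), rtol=0.15
        )

    def test_too_few_records(self, coeffs):
        records = generate_degradation_dataset(coeffs, COUPON_DESIGN)[:4]
        with pytest.raises(ValueError, match="at least 5"):
            fit_coefficients(records)

    def test_single_strain_unidentifiable(self, coeffs):
        records = generate_degradation_dataset(
            coeffs, {"strains": [0.0], "times": [3, 10, 20, 30, 40]}
        )
        with pytest.raises(ValueError, match="distinct strains"):
            fit_coefficients(records)

    def test_single_time_unidentifiable(self, coeffs):
        records = generate_degradation_dataset(
            coeffs, {"strains": [0.0, 0.1, 0.2, 0.3, 0.4], "times": [10.0]}
        )
        with pytest.raises(ValueError, match="distinct positive times"):
            fit_coefficients(records)


def test_records_csv_round_trip(tmp_path, coeffs):
    records = generate_degradation_dataset(coeffs, COUPON_DESIGN, noise_sd=0.01, seed=3)
    path = tmp_path / "records.csv"
    kinetics.write_degradation_records(records, path)
    back = kinetics.read_degradation_records(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.strain, a.time_days) == (b.strain, b.time_days)
        assert b.degree == pytest.approx(a.degree, rel=1e-12)

    (tmp_path / "bad.csv").write_text("strain,degree\n0.1,0.2\n")
    with pytest.raises(ValueError, match="time_days"):
        kinetics.read_degradation_records(tmp_path / "bad.csv")
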