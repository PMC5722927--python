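"""Single tethered-ligand physics: end density, first-passage times, loop times."""

import math

import mpmath
import numpy as np
import pytest

from zipbind import (
    ChainSpec,
    DomainError,
    RangeOverflowError,
    log_mfpt_closed_form,
    log_tau_q,
    loop_bind_time_nonspecific,
    mfpt_closed_form,
    mfpt_numeric,
    radial_density,
    radial_density_normalization,
    tau_q,
    zipper_dominance_coefficient,
)


def mp_radial_density(rho, N, b, a, dps=50):
    """Independent arbitrary-precision evaluation of the end density."""
    with mpmath.workdps(dps):
        N, b, a, rho = map(mpmath.mpf, (N, b, a, rho))
        Nb2 = N * b**2
        pref = (2 * b / a) * mpmath.sqrt(N * mpmath.pi / 6) \
            * (3 / (2 * mpmath.pi * Nb2)) ** mpmath.mpf("1.5")
        val = pref * mpmath.exp(-3 * (a**2 + rho**2) / (2 * Nb2)) \
            * mpmath.besseli(1, 3 * a * rho / Nb2)
        return float(val)


class TestRadialDensity:
    def test_zero_at_contactless_origin(self, spec_single):
        # I_1(0) = 0: the end cannot sit on top of the grafting axis image
        assert radial_density(0.0, spec_single, a=10.0) == 0.0

    @pytest.mark.parametrize("rho", [0.5, 5.0, 10.0, 25.0, 60.0])
    def test_matches_high_precision_oracle(self, spec_single, rho):
        got = radial_density(rho, spec_single, a=10.0)
        want = mp_radial_density(rho, 100, 1.0, 10.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_overflow_safe_far_into_the_tail(self, spec_single):
        # naive exp(-x) * I_1(y) overflows here; the scaled-Bessel path must not
        val = radial_density(500.0, spec_single, a=400.0)
        assert math.isfinite(val) and val >= 0.0

    def test_unimodal_in_rho(self, spec_single):
        rho = np.linspace(1e-6, 60.0, 4000)
        dens = np.array([radial_density(r, spec_single, 10.0) for r in rho])
        d = np.diff(dens)
        # rises from zero, one maximum, then decays: one sign change in the slope
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
        assert np.all(dens >= 0)

    def test_domain_errors(self, spec_single):
        with pytest.raises(DomainError):
            radial_density(1.0, spec_single, a=0.0)
        with pytest.raises(DomainError):
            radial_density(-1.0, spec_single, a=10.0)

    def test_normalizes_under_hemispherical_measure(self, spec_single):
        # integral of 2 pi rho^2 P(rho): finite, stable between refinements,
        # and equal to 1 (the density is a probability density in this measure)
        coarse = radial_density_normalization(spec_single, 10.0, rel_tol=1e-8)
        fine = radial_density_normalization(spec_single, 10.0, rel_tol=1e-11)
        assert abs(coarse - fine) <= 1e-6 * abs(fine)
        assert fine == pytest.approx(1.0, rel=1e-8)


class TestMfptNumeric:
    def test_increasing_in_distance(self):
        spec = ChainSpec(N=100)
        vals = [mfpt_numeric(spec, a) for a in (5.0, 10.0, 20.0, 30.0, 40.0)]
        assert all(v > 0 for v in vals)
        assert np.all(np.diff(vals) > 0)

    def test_diverges_as_capture_radius_shrinks(self):
        vals = [mfpt_numeric(ChainSpec(N=100, eps=e), 10.0)
                for e in (0.5, 0.25, 0.125)]
        assert vals[1] > vals[0] and vals[2] > vals[1]

    def test_approaches_closed_form_scaling(self):
        # ratio numeric / closed-form over two decades of eps: tends to a
        # constant of order unity, stable to 5% across the last decade
        spec_a = 20.0
        ratios = {}
        for eps in (1.0, 0.1, 0.04, 0.02, 0.01):
            spec = ChainSpec(N=100, eps=eps)
            ratios[eps] = mfpt_numeric(spec, spec_a) / mfpt_closed_form(spec, spec_a)
        assert 0.1 < ratios[1.0] < 10.0
        last_decade = [ratios[0.04], ratios[0.02], ratios[0.01]]
        assert max(last_decade) / min(last_decade) < 1.05
        # the closed form is the exact eps -> 0 limit: the constant is 1
        assert ratios[0.01] == pytest.approx(1.0, abs=5e-4)


class TestMfptClosedForm:
    def test_barrierless_value(self):
        spec = ChainSpec(N=100, b=1.0, D=1.0, eps=1.0)
        assert mfpt_closed_form(spec, 0.0) == pytest.approx(10000.0 / 9.0)

    def test_log_space_at_large_stretch(self):
        spec = ChainSpec(N=100)
        # a = 40: exponent 3*1600/200 = 24
        want = math.log(10000.0 / 9.0) + 24.0
        assert log_mfpt_closed_form(spec, 40.0) == pytest.approx(want, rel=1e-14)
        assert mfpt_closed_form(spec, 40.0) == pytest.approx(
            (10000.0 / 9.0) * math.exp(24.0), rel=1e-12)

    def test_eps_scaling_exact(self):
        t1 = mfpt_closed_form(ChainSpec(N=100, eps=1.0), 10.0)
        t2 = mfpt_closed_form(ChainSpec(N=100, eps=2.0), 10.0)
        assert t1 == pytest.approx(4.0 * t2, rel=1e-14)

    def test_monotone_in_a_and_D(self):
        assert (mfpt_closed_form(ChainSpec(N=100), 20.0)
                > mfpt_closed_form(ChainSpec(N=100), 10.0))
        assert (mfpt_closed_form(ChainSpec(N=100, D=2.0), 10.0)
                < mfpt_closed_form(ChainSpec(N=100, D=1.0), 10.0))

    def test_overflow_reports_log(self):
        spec = ChainSpec(N=10)
        with pytest.raises(RangeOverflowError) as err:
            mfpt_closed_form(spec, 1000.0)
        assert err.value.log_value == pytest.approx(
            log_mfpt_closed_form(spec, 1000.0))


class TestTauQ:
    def test_single_step_is_identity(self, spec_spaced):
        assert tau_q(1, spec_spaced) == pytest.approx(
            math.exp(log_mfpt_closed_form(
                ChainSpec(N=20, eps=spec_spaced.eps), spec_spaced.delta_a)))

    def test_dense_receptors_quadratic_ratio(self, spec_dense):
        assert tau_q(3, spec_dense) == pytest.approx(9.0 * tau_q(1, spec_dense),
                                                     rel=1e-14)

    def test_entropic_factor(self):
        # M delta_a^2 / (N b^2) = 1  ->  tau_2a = 4 e^{3/2} tau_1a
        spec = ChainSpec(N=100, M=4, delta_a=5.0)
        assert spec.M * spec.delta_a**2 / spec.N == pytest.approx(1.0)
        assert tau_q(2, spec) == pytest.approx(
            4.0 * math.exp(1.5) * tau_q(1, spec), rel=1e-14)

    def test_strictly_increasing_when_spaced(self, spec_spaced):
        logs = [log_tau_q(q, spec_spaced) for q in range(1, spec_spaced.M + 1)]
        assert np.all(np.diff(logs) > 0)

    def test_out_of_range(self, spec_spaced):
        for q in (0, spec_spaced.M + 1):
            with pytest.raises(DomainError):
                tau_q(q, spec_spaced)


class TestNonspecificLoopTime:
    def test_first_ligand_identity(self, spec_spaced):
        assert loop_bind_time_nonspecific(1, spec_spaced) == pytest.approx(
            tau_q(1, spec_spaced), rel=1e-14)

    def test_dense_receptors(self, spec_dense):
        assert loop_bind_time_nonspecific(2, spec_dense) == pytest.approx(
            4.0 * tau_q(1, spec_dense), rel=1e-14)

    def test_entropic_relief_factor(self):
        # 3 M delta_a^2 / (2 N b^2) = 2  ->  q=2 time is 4 e^{-1} tau_1a
        spec = ChainSpec(N=300, M=4, delta_a=10.0)
        assert 3 * spec.M * spec.delta_a**2 / (2 * spec.N) == pytest.approx(2.0)
        assert loop_bind_time_nonspecific(2, spec) == pytest.approx(
            4.0 * math.exp(-1.0) * tau_q(1, spec), rel=1e-14)

    def test_domain_error(self, spec_spaced):
        with pytest.raises(DomainError):
            loop_bind_time_nonspecific(0, spec_spaced)


class TestZipperDominanceCoefficient:
    def test_binding_value_rounds_to_054(self):
        assert zipper_dominance_coefficient(2) == pytest.approx(3.0 / (8.0 * math.log(2.0)))
        assert round(zipper_dominance_coefficient(2), 2) == 0.54

    def test_strictly_decreasing(self):
        vals = [zipper_dominance_coefficient(q) for q in range(2, 11)]
        assert np.all(np.diff(vals) < 0)

    def test_real_valued_probe(self):
        assert zipper_dominance_coefficient(math.e**2) == pytest.approx(
            3.0 * (1.0 - math.exp(-2.0)) / 8.0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            zipper_dominance_coefficient(1)


class TestChainSpec:
    def test_derived_quantities(self):
        spec = ChainSpec(N=100, M=5, delta_a=2.0)
        assert spec.a == pytest.approx(10.0)
        assert spec.delta_N == 20

    def test_eps_defaults_to_b(self):
        assert ChainSpec(N=10, b=0.5).eps == 0.5

    @pytest.mark.parametrize("kwargs", [
        dict(N=0), dict(N=10, M=0), dict(N=10, b=-1.0), dict(N=10, D=0.0),
        dict(N=10, eps=0.0), dict(N=10, delta_a=-1.0), dict(N=10, M=3),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            ChainSpec(**kwargs)
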