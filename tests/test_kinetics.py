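"""Diffusion estimation, Smoluchowski rate, Zwanzig MFPT, wobbling model."""

import numpy as np
import pytest

from ambdimer.constants import AVOGADRO, DEFAULT_STATE as STATE
from ambdimer.exceptions import DomainError, InsufficientSamplingError
from ambdimer.kinetics import (
    DiffusionProfile,
    RateResult,
    association_rate,
    build_diffusion_profile,
    estimate_window_diffusion,
    flipping_rate,
    integrated_autocorrelation_time,
    mfpt_zwanzig,
    rotational_diffusion_wobbling,
)
from ambdimer.sampler import TimeSeries, generate_ou, generate_wobble

_CONV = AVOGADRO * 1e9 * 1e-27  # (Å³/ns) -> M⁻¹ s⁻¹


# -- σ²/τ estimator ------------------------------------------------------


@pytest.mark.parametrize("k", [0.5, 2.0, 8.0])
@pytest.mark.parametrize("d", [0.02, 0.1, 0.5])
def test_diffusion_estimator_unbiased_on_ou_grid(k, d):
    """D = σ²/τ_A recovers the OU input D within 10% over a (k, D) grid."""
    tau = 1.0 / (STATE.beta * k * d)
    ts = generate_ou(k, d, n_steps=100_000, dt=tau / 10, seed=int(10 * k + 1000 * d))
    est = estimate_window_diffusion(ts, n_boot=8)
    assert abs(est.d - d) / d < 0.10


def test_diffusion_estimator_time_rescaling_covariance():
    ts = generate_ou(2.0, 0.1, n_steps=50_000, dt=0.01, seed=6)
    est1 = estimate_window_diffusion(ts, n_boot=4)
    ts10 = TimeSeries(time=ts.time * 10.0, xi=ts.xi)
    est10 = estimate_window_diffusion(ts10, n_boot=4)
    assert est10.d == pytest.approx(est1.d / 10.0, rel=1e-9)


def test_diffusion_estimator_rejects_short_series():
    ts = generate_ou(2.0, 0.1, n_steps=5_000, dt=0.01, seed=6)
    with pytest.raises(InsufficientSamplingError):
        estimate_window_diffusion(ts)


def test_diffusion_estimator_rejects_slow_series():
    # autocorrelation time comparable to the series length
    ts = generate_ou(2.0, 0.001, n_steps=12_000, dt=0.01, seed=6)
    with pytest.raises(InsufficientSamplingError):
        estimate_window_diffusion(ts)


def test_integrated_act_matches_ou_relaxation_time():
    tau = 2.0  # with βk = 1 and D = 0.5, τ = 1/(βkD) = 2
    ts = generate_ou(STATE.kT, 0.5, n_steps=200_000, dt=0.05, seed=17)
    est = integrated_autocorrelation_time(ts.xi, 0.05)
    assert abs(est - tau) / tau < 0.1


# -- diffusion profile ---------------------------------------------------


def test_diffusion_profile_interp_and_constant_extrapolation():
    prof = build_diffusion_profile([0.2, 0.4, 0.1], nodes=[5.0, 10.0, 15.0])
    assert prof(10.0) == 0.4  # node
    assert prof(7.5) == pytest.approx(0.3)  # midpoint mean
    assert prof(2.0) == 0.2  # constant below
    assert prof(40.0) == 0.1  # constant above


def test_diffusion_profile_validation():
    with pytest.raises(DomainError):
        DiffusionProfile(nodes=np.array([5.0, 4.0]), values=np.array([0.1, 0.2]))
    with pytest.raises(DomainError):
        DiffusionProfile(nodes=np.array([4.0, 5.0]), values=np.array([0.1, -0.2]))


# -- association rate ----------------------------------------------------


def test_association_rate_free_diffusion_anchor():
    """w ≡ 0, constant D → the Debye–Smoluchowski limit 4πDξ_a N_A."""
    d, a = 0.1, 11.0
    k = association_rate(None, d, xi_a=a, xi_b=1000.0, jacobian_mode="radial")
    debye = 4.0 * np.pi * d * a * _CONV
    assert abs(k - debye) / debye < 0.02
    # exact finite-reservoir closed form at a modest outer boundary
    b = 50.0
    k_b = association_rate(None, d, xi_a=a, xi_b=b, jacobian_mode="radial")
    exact = 4.0 * np.pi * d / (1.0 / a - 1.0 / b) * _CONV
    assert k_b == pytest.approx(exact, rel=1e-4)


def test_association_rate_vanishes_without_transport():
    k = association_rate(None, 1e-12, xi_a=11.0, xi_b=100.0)
    assert k < 1.0


def test_association_rate_matches_bd_box_normalized(surface):
    """Smoluchowski solution vs the Brownian first-passage oracle on the
    calibrated profile (constant D).

    In the angular-integrated convention the effective 1D walk feels the
    plateau-flat G, for which the reservoir steady-state flux equals
    V_eff/(2 τ) exactly; with the short-range attraction the relation
    holds to O(range/ξ_b).
    """
    from ambdimer.landscape import project_1d
    from ambdimer.sampler import simulate_first_passage

    prof = project_1d(surface)
    gfun = lambda x: np.where(np.asarray(x) > prof.xi[-1], 0.0, prof.interpolate(x))  # noqa: E731
    a, b, d = 11.0, 100.0, 1.0
    k_on = association_rate(prof, d, xi_a=a, xi_b=b)
    res = simulate_first_passage(
        gfun, d, start=b - 1e-6, absorbing_at=a, reflecting_at=b,
        n_replicas=150, seed=9, dt=0.045,
    )
    z = np.linspace(a, b, 8001)
    v_eff = 4.0 * np.pi * b**2 * np.trapezoid(np.exp(-STATE.beta * gfun(z)), z)
    k_bd = v_eff / (2.0 * res.mean) * _CONV
    se_k = k_bd * res.se / res.mean
    assert res.n_capped == 0
    assert abs(k_bd - k_on) < 3.0 * se_k


def test_association_rate_validation():
    with pytest.raises(DomainError):
        association_rate(None, 0.1, xi_a=20.0, xi_b=10.0)
    with pytest.raises(DomainError):
        association_rate(None, 0.1, xi_a=5.0, xi_b=20.0, jacobian_mode="spherical")


# -- Zwanzig MFPT --------------------------------------------------------


def test_mfpt_flat_closed_form():
    d = 3.8e12  # deg²/s
    tau = mfpt_zwanzig(None, d, 0.0, 180.0, reflecting_at=0.0)
    exact = 180.0**2 / (2.0 * d)
    assert abs(tau - exact) / exact < 0.005


def test_mfpt_zero_distance_and_ordering():
    assert mfpt_zwanzig(None, 1e12, 90.0, 90.0) == 0.0
    with pytest.raises(DomainError):
        mfpt_zwanzig(None, 1e12, 150.0, 30.0, reflecting_at=0.0)


def test_mfpt_mirrored_geometry_equals_symmetric_counterpart():
    pot = lambda th: 1.5 * np.exp(-0.5 * ((np.asarray(th) - 90.0) / 20.0) ** 2)  # noqa: E731
    d = 2.0e12
    fwd = mfpt_zwanzig(pot, d, 30.0, 150.0, reflecting_at=0.0)
    back = mfpt_zwanzig(pot, d, 150.0, 30.0, reflecting_at=180.0)
    assert fwd == pytest.approx(back, rel=1e-9)


def test_mfpt_matches_bd_oracle_with_barrier():
    from ambdimer.sampler import simulate_first_passage

    barrier = lambda th: 2.0 * np.exp(-0.5 * ((np.asarray(th) - 90.0) / 15.0) ** 2)  # noqa: E731
    d = 3.8e12
    tau_z = mfpt_zwanzig(barrier, d, 30.0, 150.0, reflecting_at=0.0)
    res = simulate_first_passage(
        barrier, d, start=30.0, absorbing_at=150.0, reflecting_at=0.0,
        n_replicas=200, seed=3, dt=5e-13,
    )
    assert abs(res.mean - tau_z) < 3.0 * res.se


# -- wobbling-in-a-cone --------------------------------------------------


def _wobble_series(d_in, sigma=8.0, center=30.0, seed=5, n=100_000):
    kappa = STATE.kT / sigma**2
    pot = lambda th: 0.5 * kappa * (np.asarray(th) - center) ** 2  # noqa: E731
    tau = sigma**2 / d_in
    return generate_wobble(d_in, pot, n_steps=n, dt=tau / 20, seed=seed)


@pytest.mark.parametrize("d_in", [3.8e12, 1.0e12])
def test_wobbling_estimator_recovers_input(d_in):
    est = rotational_diffusion_wobbling(_wobble_series(d_in))
    assert abs(est.d_rot - d_in) / d_in < 0.15
    assert est.sigma == pytest.approx(8.0, abs=1.0)


def test_wobbling_estimator_invariant_to_confinement():
    d_in = 2.0e12
    est_soft = rotational_diffusion_wobbling(_wobble_series(d_in, sigma=8.0, seed=31))
    est_stiff = rotational_diffusion_wobbling(_wobble_series(d_in, sigma=4.0, seed=32))
    assert est_stiff.sigma < est_soft.sigma
    assert abs(est_stiff.d_rot - d_in) / d_in < 0.15
    assert abs(est_soft.d_rot - d_in) / d_in < 0.15


# -- flipping rate -------------------------------------------------------


def test_flipping_rate_values():
    assert flipping_rate(200e-9) == pytest.approx(5.0e6, rel=1e-12)
    assert flipping_rate(1.0) == 1.0
    with pytest.raises(DomainError):
        flipping_rate(0.0)


def test_flipping_rate_unit_round_trip():
    d = 3.8e12
    tau_s = mfpt_zwanzig(None, d, 0.0, 180.0)
    rate = flipping_rate(tau_s)
    # a nanosecond-scale MFPT must give a ~1e8-1e9 s⁻¹ rate
    assert rate == pytest.approx(2.0 * d / 180.0**2, rel=1e-3)
    res = RateResult(
        k_on=1e8, absorbing_boundary=11.0, outer_boundary=25.0,
        mfpt_ns=tau_s * 1e9, flipping_rate_per_s=1.0 / tau_s,
    )
    assert res.mfpt_ns * 1e-9 * res.flipping_rate_per_s == pytest.approx(1.0)


def test_rate_result_rejects_inconsistent_units():
    with pytest.raises(DomainError):
        RateResult(
            k_on=1e8, absorbing_boundary=11.0, outer_boundary=25.0,
            mfpt_ns=200.0, flipping_rate_per_s=1.0 / 200.0,  # forgot ns -> s
        )
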