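"""Stochastic generators: determinism, exact limits, oracle distributions."""

import numpy as np
import pytest
from scipy import stats

from ambdimer.constants import DEFAULT_STATE as STATE
from ambdimer.exceptions import DomainError, SamplingGapError
from ambdimer.landscape import load_default_surface
from ambdimer.sampler import (
    LadderConfig,
    UmbrellaWindow,
    generate_ladder,
    generate_ou,
    generate_wobble,
    generate_window,
    simulate_first_passage,
)

SMALL = dict(n_steps=20_000, timestep=0.002, output_stride=4)


def test_same_seed_bit_identical(null_surface):
    w = UmbrellaWindow(0, 10.0, 2.0, **SMALL)
    a = generate_window(null_surface, w, seed=42)
    b = generate_window(null_surface, w, seed=42)
    np.testing.assert_array_equal(a.xi, b.xi)
    np.testing.assert_array_equal(a.theta, b.theta)
    c = generate_window(null_surface, w, seed=43)
    assert not np.array_equal(a.xi, c.xi)


def test_ladder_window_matches_standalone_window(surface):
    cfg = LadderConfig(n_windows=3, xi_min=5.0, xi_max=9.0, **SMALL)
    ladder = generate_ladder(surface, cfg)
    w1, ts1 = ladder[1]
    alone = generate_window(
        surface, w1, d_xi=cfg.d_xi, d_theta=cfg.d_theta, seed=ts1.meta["seed"]
    )
    np.testing.assert_array_equal(alone.xi, ts1.xi)
    np.testing.assert_array_equal(alone.theta, ts1.theta)


def test_default_ladder_covers_published_windows():
    cfg = LadderConfig()
    windows = cfg.windows()
    assert len(windows) == 17
    assert windows[0].bias_center == 4.0
    assert windows[-1].bias_center == 25.0


def test_halving_stride_doubles_samples(null_surface):
    w1 = UmbrellaWindow(0, 10.0, 2.0, n_steps=20_000, timestep=0.002, output_stride=4)
    w2 = UmbrellaWindow(0, 10.0, 2.0, n_steps=20_000, timestep=0.002, output_stride=2)
    a = generate_window(null_surface, w1, seed=1)
    b = generate_window(null_surface, w2, seed=1)
    assert 2 * len(a) == len(b)


def test_stiff_spring_limit(null_surface):
    w = UmbrellaWindow(0, 12.0, 1000.0, n_steps=200_000, timestep=1e-4, output_stride=4)
    ts = generate_window(null_surface, w, seed=5)
    assert abs(ts.burned_in(0.1).xi.mean() - 12.0) < 0.05


def test_biased_flat_landscape_is_gaussian(null_surface):
    """Histogram of ξ under a harmonic bias matches exp(-βw) (KS test)."""
    k, center = 2.0, 14.5
    w = UmbrellaWindow(0, center, k, n_steps=100_000, timestep=0.002, output_stride=1)
    ts = generate_window(null_surface, w, d_xi=2.0, seed=11)
    x = ts.burned_in(0.1).xi
    # subsample to roughly independent points before testing
    tau_steps = 1.0 / (STATE.beta * k * 2.0 * 0.002)
    x = x[:: int(5 * tau_steps)]
    sigma = np.sqrt(STATE.kT / k)
    p = stats.kstest(x, "norm", args=(center, sigma)).pvalue
    assert p > 0.01


def test_samples_stay_in_domain_no_nan(surface):
    cfg = LadderConfig(n_windows=4, xi_min=5.0, xi_max=9.0, **SMALL)
    for _, ts in generate_ladder(surface, cfg):
        assert np.all(np.isfinite(ts.xi)) and np.all(np.isfinite(ts.theta))
        assert np.all((ts.xi >= 3.5) & (ts.xi <= 25.0))
        assert np.all((ts.theta >= 0.0) & (ts.theta <= 180.0))


def test_adjacent_window_gap_detection(null_surface):
    cfg = LadderConfig(
        n_windows=2, force_constant=400.0, n_steps=4_000, timestep=1e-4, output_stride=2
    )
    with pytest.raises(SamplingGapError):
        generate_ladder(null_surface, cfg)


# -- Ornstein-Uhlenbeck oracle ------------------------------------------


def test_ou_stationary_moments():
    # force constant k_B T per Å² → βk = 1 → stationary variance 1 Å²
    ts = generate_ou(STATE.kT, 0.1, n_steps=100_000, dt=0.01, seed=3)
    se = np.sqrt(2.0 / (len(ts) / (2 * ts.meta["tau"] / 0.01)))
    assert abs(np.var(ts.xi) - 1.0) < 3 * se
    assert abs(np.mean(ts.xi)) < 3 * np.std(ts.xi) / np.sqrt(len(ts) / 200)


def test_ou_relaxation_time_halves_when_d_doubles():
    from ambdimer.kinetics import integrated_autocorrelation_time

    t1 = generate_ou(2.0, 0.1, n_steps=200_000, dt=0.01, seed=9)
    t2 = generate_ou(2.0, 0.2, n_steps=200_000, dt=0.005, seed=10)
    tau1 = integrated_autocorrelation_time(t1.xi, 0.01)
    tau2 = integrated_autocorrelation_time(t2.xi, 0.005)
    assert abs(tau1 / tau2 - 2.0) < 0.2 * 2.0


def test_ou_determinism():
    a = generate_ou(1.0, 0.1, n_steps=1000, dt=0.01, seed=4)
    b = generate_ou(1.0, 0.1, n_steps=1000, dt=0.01, seed=4)
    np.testing.assert_array_equal(a.xi, b.xi)


# -- wobble oracle -------------------------------------------------------


def _harmonic_about(center, kappa):
    def f(th):
        return 0.5 * kappa * (th - center) ** 2

    return f


def test_wobble_density_matches_sin_weighted_boltzmann():
    kappa = STATE.kT / 8.0**2  # σ = 8 deg
    pot = _harmonic_about(30.0, kappa)
    d = 3.8e12
    tau = 8.0**2 / d
    ts = generate_wobble(d, pot, n_steps=100_000, dt=tau / 20, seed=21)
    th = ts.burned_in(0.1).xi[::100]
    grid = np.linspace(1e-3, 180.0, 5001)
    dens = np.sin(np.radians(grid)) * np.exp(-STATE.beta * pot(grid))
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    p = stats.kstest(th, lambda v: np.interp(v, grid, cdf)).pvalue
    assert p > 0.01


def test_wobble_determinism_and_confinement_ordering():
    d = 1.0e12
    spreads = []
    for sigma in (16.0, 8.0, 4.0):
        pot = _harmonic_about(30.0, STATE.kT / sigma**2)
        ts = generate_wobble(d, pot, n_steps=30_000, dt=5e-14, seed=2)
        spreads.append(np.var(ts.burned_in(0.2).xi))
    assert spreads[0] > spreads[1] > spreads[2]
    a = generate_wobble(d, _harmonic_about(30.0, 0.01), n_steps=500, dt=5e-14, seed=8)
    b = generate_wobble(d, _harmonic_about(30.0, 0.01), n_steps=500, dt=5e-14, seed=8)
    np.testing.assert_array_equal(a.xi, b.xi)


# -- first-passage oracle ------------------------------------------------


def test_first_passage_flat_closed_form():
    d, L = 0.1, 5.0
    res = simulate_first_passage(
        None, d, start=0.0, absorbing_at=L, reflecting_at=0.0,
        n_replicas=2000, seed=12, dt=0.02,
    )
    exact = L**2 / (2 * d)
    assert res.n_capped == 0
    assert abs(res.mean - exact) < 3 * res.se + 0.02 * exact


def test_first_passage_start_at_absorbing_boundary():
    res = simulate_first_passage(
        None, 0.1, start=5.0, absorbing_at=5.0, reflecting_at=0.0,
        n_replicas=10, seed=1, dt=0.01,
    )
    assert res.mean == 0.0


def test_first_passage_diffusive_scaling():
    kw = dict(start=0.0, absorbing_at=4.0, reflecting_at=0.0, n_replicas=1500)
    r1 = simulate_first_passage(None, 0.1, seed=3, dt=0.02, **kw)
    r2 = simulate_first_passage(None, 0.2, seed=4, dt=0.01, **kw)
    assert abs(r1.mean / r2.mean - 2.0) < 0.1 * 2.0


def test_first_passage_boundary_validation():
    with pytest.raises(DomainError):
        simulate_first_passage(None, 0.1, 1.0, absorbing_at=2.0, reflecting_at=2.0)
    with pytest.raises(DomainError):
        simulate_first_passage(None, 0.1, 9.0, absorbing_at=2.0, reflecting_at=5.0)


def test_detailed_balance_on_calibrated_surface(surface):
    """Unbiased sampling in the bound region reproduces the quadrature
    basin populations within Monte-Carlo error."""
    from ambdimer.landscape import _quadrature_populations
    from ambdimer.sampler import _integrate_umbrella

    nrep = 4
    times, oxi, oth, _ = _integrate_umbrella(
        surface, STATE,
        centers=np.full(nrep, 5.5), force_constants=np.full(nrep, 1e-9),
        d_xi=2.0, d_theta=6000.0, dt=0.002, n_steps=600_000, stride=8,
        seeds=np.arange(71, 71 + nrep), xi_domain=(3.5, 11.0),
    )
    xi = oxi[len(times) // 5:].ravel()
    th = oth[len(times) // 5:].ravel()
    pops = _quadrature_populations(surface, STATE)
    p_ii = np.mean((xi >= 5.5) & (th > 90.0))
    # ~100 independent basin visits per replica
    se = 3 * np.sqrt(p_ii * (1 - p_ii) / (nrep * 150))
    assert abs(p_ii - pops[1]) < max(se, 0.04)
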