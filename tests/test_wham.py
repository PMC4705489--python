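"""WHAM reconstruction, reweighting, basin statistics."""

import numpy as np
import pytest

from ambdimer.constants import DEFAULT_STATE as STATE
from ambdimer.exceptions import (
    ConsistencyError,
    CoordinateError,
    DomainError,
    PartitionError,
    SamplingGapError,
)
from ambdimer.profiles import FreeEnergyProfile1D, FreeEnergySurface2D
from ambdimer.sampler import TimeSeries, UmbrellaWindow, generate_ou
from ambdimer.wham import (
    basin_populations,
    default_basin_regions,
    locate_minima,
    orientation_stats,
    reweight_2d,
    sample_weights,
    solve_wham_1d,
    statistical_inefficiency,
)

from _mbar_oracle import mbar_offsets


def _gaussian_series(rng, center, sigma, n=60_000, theta=None):
    xi = rng.normal(center, sigma, n)
    th = None if theta is None else rng.uniform(*theta, n)
    return TimeSeries(time=0.01 * np.arange(1, n + 1), xi=xi, theta=th)


def _window(i, c, k, n=60_000):
    return UmbrellaWindow(i, c, k, n_steps=n, timestep=0.01, output_stride=1)


def test_single_window_zero_bias_is_direct_inversion(rng):
    """With a negligible bias WHAM degenerates to -kT ln(histogram)."""
    # samples from a known two-level density on [10, 20]
    n = 120_000
    left = rng.uniform(10.0, 15.0, int(n * 0.8))
    right = rng.uniform(15.0, 20.0, n - len(left))
    xi = np.concatenate([left, right])
    rng.shuffle(xi)
    ts = TimeSeries(time=0.01 * np.arange(1, n + 1), xi=xi)
    w = _window(0, 15.0, 1e-9, n)
    prof, off = solve_wham_1d(
        [ts], [w], n_bins=20, xi_range=(10.0, 20.0), plateau_from=15.0,
        inefficiency_correction=False,
    )
    hist, _ = np.histogram(ts.burned_in(0.1).xi, bins=20, range=(10.0, 20.0))
    direct = -STATE.kT * np.log(hist.astype(float))
    # compare level differences (additive constants are convention)
    dg_wham = prof.g[:10].mean() - prof.g[10:].mean()
    dg_direct = direct[:10].mean() - direct[10:].mean()
    assert abs(dg_wham - dg_direct) < 1e-9
    assert abs(dg_wham - (-STATE.kT * np.log(4.0))) < 0.05


def test_two_window_harmonic_recovery(rng):
    """Exact Gaussian sampling of G = ½κ(ξ-c)² + bias; WHAM recovers G."""
    kappa, c0 = 1.0, 15.0
    k_bias = 2.0
    windows = [_window(0, 14.0, k_bias), _window(1, 16.0, k_bias)]
    series = []
    for w in windows:
        # G + w is harmonic: exact Gaussian with analytic mean/variance
        k_tot = kappa + k_bias
        mean = (kappa * c0 + k_bias * w.bias_center) / k_tot
        series.append(_gaussian_series(rng, mean, np.sqrt(STATE.kT / k_tot)))
    prof, off = solve_wham_1d(
        series, windows, n_bins=60, xi_range=(13.0, 17.0), plateau_from=13.0,
        inefficiency_correction=False,
    )
    analytic = 0.5 * kappa * (prof.xi - c0) ** 2
    good = prof.counts > 200
    resid = (prof.g - analytic)[good]
    resid -= resid.mean()
    assert np.sqrt(np.mean(resid**2)) < 0.1


def test_wham_matches_independent_mbar_oracle(rng):
    windows = [_window(0, 13.5, 1.0), _window(1, 15.0, 1.0), _window(2, 16.5, 1.0)]
    series = [
        _gaussian_series(rng, w.bias_center, np.sqrt(STATE.kT / 1.0)) for w in windows
    ]
    _, off = solve_wham_1d(
        series, windows, n_bins=120, xi_range=(12.0, 18.0), plateau_from=12.0,
        inefficiency_correction=False,
    )
    f_ref = mbar_offsets(
        [ts.burned_in(0.1).xi for ts in series],
        [w.bias for w in windows],
        STATE.beta,
    )
    np.testing.assert_allclose(off.f, f_ref, atol=0.05)


def test_wham_consistency_with_pooled_inversion(rng):
    """On densely overlapping windows the profile equals the direct
    Boltzmann inversion of the pooled reweighted samples."""
    windows = [_window(i, 12.0 + i, 0.5) for i in range(5)]
    series = [
        _gaussian_series(rng, w.bias_center, np.sqrt(STATE.kT / 0.5)) for w in windows
    ]
    prof, off = solve_wham_1d(
        series, windows, n_bins=40, xi_range=(11.0, 17.0), plateau_from=11.0,
        inefficiency_correction=False,
    )
    xi, _, wgt, _ = sample_weights(series, windows, off)
    hist, edges = np.histogram(xi, bins=40, range=(11.0, 17.0), weights=wgt)
    pooled = -STATE.kT * np.log(hist)
    resid = prof.g - (pooled - pooled.mean() + prof.g.mean())
    assert np.sqrt(np.mean(resid**2)) < 0.05


def test_weight_sum_identity(rng):
    windows = [_window(0, 14.0, 2.0), _window(1, 16.0, 2.0)]
    series = [
        _gaussian_series(rng, w.bias_center, 0.6, theta=(0.0, 180.0)) for w in windows
    ]
    _, off = solve_wham_1d(
        series, windows, n_bins=50, xi_range=(12.0, 18.0), plateau_from=12.0
    )
    _, _, wgt, den = sample_weights(series, windows, off)
    total = np.sum(wgt * den)
    n_samples = sum(len(ts.burned_in(0.1)) for ts in series)
    assert total == pytest.approx(n_samples, rel=1e-9)


def test_offset_shift_invariance(rng):
    """Adding a constant to every window offset leaves the reweighted
    surface unchanged."""
    import dataclasses

    windows = [_window(0, 14.0, 2.0), _window(1, 16.0, 2.0)]
    series = [
        _gaussian_series(rng, w.bias_center, 0.6, theta=(0.0, 180.0)) for w in windows
    ]
    _, off = solve_wham_1d(
        series, windows, n_bins=50, xi_range=(12.0, 18.0), plateau_from=12.0
    )
    kw = dict(
        xi_edges=np.linspace(12, 18, 25), angle_edges=np.linspace(0, 180, 13)
    )
    s1 = reweight_2d(series, windows, off, **kw)
    off2 = dataclasses.replace(off, f=off.f + 3.21)
    s2 = reweight_2d(series, windows, off2, **kw)
    np.testing.assert_allclose(s1.g, s2.g, atol=1e-9, equal_nan=True)


def test_reweight_requires_matching_windows(rng):
    windows = [_window(0, 14.0, 2.0), _window(1, 16.0, 2.0)]
    series = [
        _gaussian_series(rng, w.bias_center, 0.6, theta=(0.0, 180.0)) for w in windows
    ]
    _, off = solve_wham_1d(
        series, windows, n_bins=50, xi_range=(12.0, 18.0), plateau_from=12.0
    )
    other = [_window(0, 14.0, 2.0), _window(1, 16.5, 2.0)]
    with pytest.raises(ConsistencyError):
        reweight_2d(series, other, off)


def test_sampling_gap_raises(rng):
    windows = [_window(0, 12.0, 50.0), _window(1, 18.0, 50.0)]
    series = [_gaussian_series(rng, w.bias_center, 0.1) for w in windows]
    with pytest.raises(SamplingGapError):
        solve_wham_1d(series, windows, n_bins=60, xi_range=(11.0, 19.0))


def test_flat_surface_reweights_flat_in_theta(rng):
    windows = [_window(0, 14.0, 1.0), _window(1, 16.0, 1.0)]
    series = [
        _gaussian_series(rng, w.bias_center, np.sqrt(STATE.kT / 1.0), theta=(0, 180))
        for w in windows
    ]
    _, off = solve_wham_1d(
        series, windows, n_bins=50, xi_range=(12.5, 17.5), plateau_from=12.5
    )
    surf = reweight_2d(
        series, windows, off,
        xi_edges=np.linspace(13.5, 16.5, 7), angle_edges=np.linspace(0, 180, 10),
    )
    spread = np.nanmax(surf.g, axis=1) - np.nanmin(surf.g, axis=1)
    assert np.all(spread < 0.3)


# -- locate_minima -------------------------------------------------------


def test_locate_minima_single_parabola():
    xi = np.linspace(0.0, 10.0, 201)
    prof = FreeEnergyProfile1D(xi=xi, g=0.5 * (xi - 4.2) ** 2 - 3.0,
                               zero_convention="raw")
    m = locate_minima(prof)
    assert len(m.positions) == 1
    assert m.positions[0] == pytest.approx(4.2, abs=1e-6)
    assert m.barrier is None


def test_locate_minima_two_wells_and_barrier():
    xi = np.linspace(3.0, 12.0, 901)
    g = (
        -5.0 * np.exp(-0.5 * ((xi - 4.5) / 0.5) ** 2)
        - 4.5 * np.exp(-0.5 * ((xi - 6.5) / 0.5) ** 2)
    )
    prof = FreeEnergyProfile1D(xi=xi, g=g, zero_convention="raw")
    m = locate_minima(prof)
    # brute-force oracle
    order = np.argsort(g)
    assert m.positions[0] == pytest.approx(xi[order[0]], abs=0.02)
    assert sorted(m.positions[:2]) == pytest.approx([4.5, 6.5], abs=0.02)
    seg = g[(xi > 4.5) & (xi < 6.5)]
    assert m.barrier == pytest.approx(seg.max() - max(m.values[:2]), abs=1e-9)


def test_locate_minima_none_found():
    xi = np.linspace(0.0, 5.0, 100)
    prof = FreeEnergyProfile1D(xi=xi, g=np.zeros_like(xi) + 1.0,
                               zero_convention="raw")
    with pytest.raises(DomainError):
        locate_minima(prof)


# -- basin populations & orientation ------------------------------------


def _symmetric_surface2d():
    xi = np.linspace(4.25, 10.75, 14)
    th = np.linspace(5.0, 175.0, 18)
    g = np.zeros((14, 18))
    return FreeEnergySurface2D(xi=xi, angle=th, g=g, mask=np.zeros_like(g, bool))


def test_symmetric_surface_equal_quadrant_populations():
    surf = _symmetric_surface2d()
    pops = basin_populations(surf, default_basin_regions(xi_lo=4.0, xi_split=7.5))
    vals = np.array(list(pops.values()))
    assert abs(sum(vals) - 1.0) < 1e-9
    # flat surface: populations proportional to quadrant areas
    assert pops["I"] == pytest.approx(pops["III"], abs=1e-9)
    assert pops["II"] == pytest.approx(pops["IV"], abs=1e-9)


def test_population_partition_errors():
    surf = _symmetric_surface2d()
    overlapping = {
        "A": (4.0, 8.0, 0.0, 180.0),
        "B": (7.0, 11.0, 0.0, 180.0),
    }
    with pytest.raises(PartitionError):
        basin_populations(surf, overlapping)
    not_covering = {"A": (4.0, 5.0, 0.0, 90.0)}
    with pytest.raises(PartitionError):
        basin_populations(surf, not_covering)


def test_orientation_stats_symmetric():
    surf = _symmetric_surface2d()
    st = orientation_stats(surf)
    assert st.p_parallel == pytest.approx(0.5, abs=1e-9)
    assert st.mean_xi_parallel == pytest.approx(st.mean_xi_antiparallel, abs=1e-9)


def test_orientation_stats_requires_theta():
    surf = _symmetric_surface2d()
    surf.angle_tag = "phi"
    with pytest.raises(CoordinateError):
        orientation_stats(surf)


def test_statistical_inefficiency_white_noise(rng):
    g = statistical_inefficiency(rng.standard_normal(50_000))
    assert 0.8 < g < 1.3
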