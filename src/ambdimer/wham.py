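"""WHAM reconstruction and Boltzmann reweighting of umbrella-sampling data.

``solve_wham_1d`` combines the biased per-window ξ histograms into an
unbiased 1D free-energy profile by iterating the standard
self-consistent WHAM equations for the per-window offsets f_i.
``reweight_2d`` then assigns every sample its unbiased weight
w_s = 1 / Σ_j N_j exp(−β(w_j(ξ_s) − f_j)) and accumulates a binless
2D (ξ, angle) surface, from which basin populations and
parallel/antiparallel statistics are computed.

Per-window sample counts are corrected for autocorrelation (statistical
inefficiency) by default, since correlated Brownian-dynamics samples
otherwise overstate the information content of each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_STATE, ThermoState
from .exceptions import (
    ConsistencyError,
    ConvergenceError,
    CoordinateError,
    DomainError,
    PartitionError,
    SamplingGapError,
)
from .profiles import FreeEnergyProfile1D, FreeEnergySurface2D, MinimaResult
from .sampler import TimeSeries, UmbrellaWindow

__all__ = [
    "WindowOffsets",
    "solve_wham_1d",
    "reweight_2d",
    "basin_populations",
    "default_basin_regions",
    "locate_minima",
    "orientation_stats",
    "statistical_inefficiency",
]


@dataclass
class WindowOffsets:
    """Converged per-window free energies f_i (relative to window 1)."""

    f: np.ndarray  # kcal/mol, f[0] == 0
    n_iterations: int
    residual: float
    window_key: tuple = ()
    objective_history: np.ndarray | None = field(default=None, repr=False)
    effective_counts: np.ndarray | None = None
    inefficiencies: np.ndarray | None = None


def statistical_inefficiency(x: np.ndarray) -> float:
    """g = 1 + 2 Σ ρ_k with the initial-positive-sequence cutoff (g ≥ 1)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return 1.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real / n
    rho = acov / acov[0]
    neg = np.nonzero(rho[1:] < 0.0)[0]
    cut = int(neg[0]) + 1 if neg.size else n
    g = 1.0 + 2.0 * float(np.sum(rho[1:cut]))
    return max(g, 1.0)


def _assemble(series, windows, equil_fraction, inefficiency_correction):
    if len(series) != len(windows) or not windows:
        raise DomainError("need one time series per window (and at least one window)")
    samples, gs, centers, ks = [], [], [], []
    for ts, w in zip(series, windows):
        xi = ts.burned_in(equil_fraction).xi
        g = statistical_inefficiency(xi) if inefficiency_correction else 1.0
        samples.append(xi)
        gs.append(g)
        centers.append(w.bias_center)
        ks.append(w.force_constant)
    return samples, np.asarray(gs), np.asarray(centers), np.asarray(ks)


def _wham_objective(neff, hist, logdenom_b, f_beta):
    # Zhu-Hummer convex objective A(f) up to an additive constant
    return float(-np.dot(neff, f_beta) + np.dot(hist, logdenom_b))


def solve_wham_1d(
    series: list[TimeSeries],
    windows: list[UmbrellaWindow],
    state: ThermoState = DEFAULT_STATE,
    n_bins: int = 200,
    xi_range: tuple = (4.0, 25.0),
    tol: float = 1e-7,
    max_iter: int = 100_000,
    equil_fraction: float = 0.1,
    inefficiency_correction: bool = True,
    plateau_from: float = 20.0,
) -> tuple[FreeEnergyProfile1D, WindowOffsets]:
    """Self-consistent binned WHAM for the 1D profile.

    Iterates until max_i |Δf_i| < ``tol`` (kcal/mol).  The profile is
    shifted to the plateau-zero convention.  Bins inside ``xi_range``
    with zero samples raise :class:`SamplingGapError`.
    """
    samples, gs, centers, ks = _assemble(
        series, windows, equil_fraction, inefficiency_correction
    )
    beta = state.beta
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(n_bins)
    neff = np.zeros(len(windows))
    for i, (xi, g) in enumerate(zip(samples, gs)):
        h, _ = np.histogram(xi, bins=edges)
        # only in-range samples enter both the histogram and the counts,
        # both scaled by the window's statistical inefficiency
        hist += h / g
        neff[i] = h.sum() / g
    empty = hist == 0
    if np.any(empty):
        lo, hi = mids[empty][0], mids[empty][-1]
        raise SamplingGapError(
            f"{int(empty.sum())} unsampled bins in [{lo:.2f}, {hi:.2f}] Å; "
            "the windows do not cover the requested range"
        )
    # bias energies at bin centres
    b = 0.5 * ks[:, None] * (mids[None, :] - centers[:, None]) ** 2
    cmat = np.exp(-beta * b)  # (n_windows, n_bins)

    f_beta = np.zeros(len(windows))  # β f_i
    history = []
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        a = neff * np.exp(f_beta)
        denom = a @ cmat  # (n_bins,)
        p = hist / denom
        z = cmat @ p  # (n_windows,)
        new_f_beta = -np.log(z)
        new_f_beta -= new_f_beta[0]
        residual = float(np.max(np.abs(new_f_beta - f_beta))) / beta
        history.append(
            _wham_objective(neff, hist, np.log(denom), new_f_beta)
        )
        f_beta = new_f_beta
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not reach tol={tol} in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual_history=history[-50:],
        )
    a = neff * np.exp(f_beta)
    p = hist / (a @ cmat)
    g = -state.kT * np.log(p)
    profile = FreeEnergyProfile1D(
        xi=mids,
        g=g,
        counts=hist,
        bin_width=float(edges[1] - edges[0]),
        meta={"n_windows": len(windows), "tol": tol, "iterations": it},
    ).plateau_shifted(plateau_from)
    offsets = WindowOffsets(
        f=f_beta / beta,
        n_iterations=it,
        residual=residual,
        window_key=tuple(zip(map(float, centers), map(float, ks))),
        objective_history=np.asarray(history),
        effective_counts=neff,
        inefficiencies=gs,
    )
    return profile, offsets


def sample_weights(
    series: list[TimeSeries],
    windows: list[UmbrellaWindow],
    offsets: WindowOffsets,
    state: ThermoState = DEFAULT_STATE,
    equil_fraction: float = 0.1,
):
    """Per-sample unbiased weights w_s = 1 / Σ_j N_j exp(−β(w_j(ξ_s) − f_j)).

    Counts are the autocorrelation-corrected effective counts whenever
    the offsets carry them; each sample is then also scaled by its own
    window's inefficiency factor N_j^eff/n_j, so numerator and
    denominator stay consistent (the same convention ``solve_wham_1d``
    uses for its histograms).  Returns (xi, theta, weights,
    denominators) concatenated over windows.
    """
    key = tuple(
        (float(w.bias_center), float(w.force_constant)) for w in windows
    )
    if key != tuple(offsets.window_key):
        raise ConsistencyError("offsets were computed for a different window set")
    beta = state.beta
    neff = offsets.effective_counts
    if neff is None:
        raise ConsistencyError("offsets carry no effective counts")
    centers = np.array([w.bias_center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    gs = (
        offsets.inefficiencies
        if offsets.inefficiencies is not None
        else np.ones(len(series))
    )
    xi_all, th_all, scale_all = [], [], []
    for ts, g in zip(series, gs):
        t = ts.burned_in(equil_fraction)
        xi_all.append(t.xi)
        th_all.append(t.theta if t.theta is not None else np.full_like(t.xi, np.nan))
        scale_all.append(np.full(len(t.xi), 1.0 / g))
    xi = np.concatenate(xi_all)
    th = np.concatenate(th_all)
    scale = np.concatenate(scale_all)
    bias = 0.5 * ks[None, :] * (xi[:, None] - centers[None, :]) ** 2
    denom = np.sum(
        neff[None, :] * np.exp(beta * (offsets.f[None, :] - bias)), axis=1
    )
    return xi, th, scale / denom, denom / scale


def reweight_2d(
    series: list[TimeSeries],
    windows: list[UmbrellaWindow],
    offsets: WindowOffsets,
    state: ThermoState = DEFAULT_STATE,
    xi_edges: np.ndarray | None = None,
    angle_edges: np.ndarray | None = None,
    angle_tag: str = "theta",
    equil_fraction: float = 0.1,
) -> FreeEnergySurface2D:
    """Binless per-sample reweighting onto a 2D (ξ, angle) grid.

    G₂ = −kT ln(weighted histogram), min-shifted to 0; unsampled bins
    are masked, never imputed.
    """
    if xi_edges is None:
        xi_edges = np.linspace(4.0, 25.0, 76)
    if angle_edges is None:
        angle_edges = np.linspace(0.0, 180.0, 61)
    xi, th, w, _ = sample_weights(series, windows, offsets, state, equil_fraction)
    if np.any(np.isnan(th)):
        raise DomainError("2D reweighting needs an angle column in every window")
    hist, _, _ = np.histogram2d(xi, th, bins=(xi_edges, angle_edges), weights=w)
    counts, _, _ = np.histogram2d(xi, th, bins=(xi_edges, angle_edges))
    mask = counts == 0
    g = np.full_like(hist, np.nan)
    with np.errstate(divide="ignore"):
        g[~mask] = -state.kT * np.log(hist[~mask])
    g -= np.nanmin(g)
    return FreeEnergySurface2D(
        xi=0.5 * (xi_edges[:-1] + xi_edges[1:]),
        angle=0.5 * (angle_edges[:-1] + angle_edges[1:]),
        g=g,
        mask=mask,
        angle_tag=angle_tag,
        counts=counts,
        meta={"zero_convention": "min-zero"},
    )


def default_basin_regions(
    xi_lo: float = 3.5,
    xi_split: float = 5.5,
    bound_boundary: float = 11.0,
    theta_split: float = 90.0,
) -> dict:
    """Quadrant rectangles (ξ_lo, ξ_hi, θ_lo, θ_hi) meeting at the midlines."""
    return {
        "I": (xi_lo, xi_split, theta_split, 180.0),
        "II": (xi_split, bound_boundary, theta_split, 180.0),
        "III": (xi_lo, xi_split, 0.0, theta_split),
        "IV": (xi_split, bound_boundary, 0.0, theta_split),
    }


def basin_populations(
    surface2d: FreeEnergySurface2D,
    regions: dict | None = None,
    state: ThermoState = DEFAULT_STATE,
    bound_boundary: float = 11.0,
) -> dict:
    """Boltzmann population of each basin region over the bound area.

    ``regions`` maps labels to (ξ_lo, ξ_hi, angle_lo, angle_hi)
    rectangles that must partition the bound region ξ < bound_boundary
    (bin centres are assigned by half-open intervals [lo, hi)).
    """
    regions = regions or default_basin_regions(bound_boundary=bound_boundary)
    xi = surface2d.xi
    th = surface2d.angle
    bound = xi < bound_boundary
    w = np.where(surface2d.mask, 0.0, np.exp(-state.beta * np.nan_to_num(surface2d.g)))
    w = w[bound, :]
    xi_b = xi[bound]
    assign = np.full((len(xi_b), len(th)), -1, dtype=int)
    labels = list(regions)
    for idx, lab in enumerate(labels):
        xlo, xhi, tlo, thi = regions[lab]
        sel = (
            (xi_b[:, None] >= xlo)
            & (xi_b[:, None] < xhi)
            & (th[None, :] >= tlo)
            & (th[None, :] < thi)
        )
        if np.any(assign[sel] >= 0):
            raise PartitionError(f"region {lab!r} overlaps another region")
        assign[sel] = idx
    covered = assign >= 0
    if np.any(~covered & (w > 0)):
        raise PartitionError("regions do not cover the whole bound area")
    total = w[covered].sum()
    if total <= 0:
        raise DomainError("no Boltzmann weight in the bound region")
    pops = {
        lab: float(w[assign == idx].sum() / total) for idx, lab in enumerate(labels)
    }
    return pops


def locate_minima(
    profile: FreeEnergyProfile1D, smoothing_window: int = 1
) -> MinimaResult:
    """Local minima of a (optionally smoothed) 1D profile, and the barrier.

    Minima are interior grid points below the plateau (G < 0), refined
    by a parabola through the three nearest points.  The barrier is the
    maximum of the profile between the two deepest minima minus the
    shallower of the two.
    """
    g = np.asarray(profile.g, dtype=float)
    x = profile.xi
    if smoothing_window > 1:
        k = int(smoothing_window) | 1  # odd
        kernel = np.ones(k) / k
        g = np.convolve(g, kernel, mode="same")
        # edges of a same-mode moving average are biased; ignore them
        edge = k // 2
        g[:edge] = np.inf
        g[-edge:] = np.inf
    cand = []
    for i in range(1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] <= g[i + 1] and g[i] < 0.0:
            denom = g[i - 1] - 2 * g[i] + g[i + 1]
            if denom > 0:
                delta = 0.5 * (g[i - 1] - g[i + 1]) / denom
                xm = x[i] + delta * (x[i] - x[i - 1])
                gm = g[i] - 0.25 * (g[i - 1] - g[i + 1]) * delta
            else:
                xm, gm = x[i], g[i]
            cand.append((float(gm), float(xm), i))
    if not cand:
        raise DomainError("no local minimum found below the plateau")
    cand.sort()
    positions = tuple(c[1] for c in cand)
    values = tuple(c[0] for c in cand)
    barrier = barrier_pos = None
    if len(cand) >= 2:
        (v1, x1, i1), (v2, x2, i2) = cand[0], cand[1]
        lo, hi = sorted((i1, i2))
        seg = g[lo : hi + 1]
        j = int(np.argmax(seg)) + lo
        barrier = float(g[j] - max(v1, v2))
        barrier_pos = float(x[j])
    return MinimaResult(
        positions=positions, values=values, barrier=barrier, barrier_position=barrier_pos
    )


@dataclass(frozen=True)
class OrientationStats:
    """Parallel/antiparallel split of the bound state."""

    p_parallel: float
    p_antiparallel: float
    mean_xi_parallel: float
    mean_xi_antiparallel: float


def orientation_stats(
    surface2d: FreeEnergySurface2D,
    state: ThermoState = DEFAULT_STATE,
    bound_boundary: float = 11.0,
) -> OrientationStats:
    """Probabilities and Boltzmann-weighted mean ξ per orientation class.

    Classes split at θ = 90°: parallel (θ < 90°) vs antiparallel (θ > 90°).
    """
    if surface2d.angle_tag != "theta":
        raise CoordinateError(
            "orientation statistics need a θ-tagged surface, got "
            f"{surface2d.angle_tag!r}"
        )
    xi = surface2d.xi
    th = surface2d.angle
    bound = xi < bound_boundary
    w = np.where(surface2d.mask, 0.0, np.exp(-state.beta * np.nan_to_num(surface2d.g)))
    w = w[bound, :]
    xi_b = xi[bound]
    par = th < 90.0
    anti = th > 90.0
    w_par = w[:, par].sum()
    w_anti = w[:, anti].sum()
    total = w_par + w_anti
    if total <= 0:
        raise DomainError("no Boltzmann weight in the bound region")
    mean_par = float((w[:, par].sum(axis=1) * xi_b).sum() / w_par) if w_par > 0 else np.nan
    mean_anti = (
        float((w[:, anti].sum(axis=1) * xi_b).sum() / w_anti) if w_anti > 0 else np.nan
    )
    return OrientationStats(
        p_parallel=float(w_par / total),
        p_antiparallel=float(w_anti / total),
        mean_xi_parallel=mean_par,
        mean_xi_antiparallel=mean_anti,
    )
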