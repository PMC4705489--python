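"""Diffusion estimation and rate theory for dimer association and flipping.

* ``estimate_window_diffusion`` — the variance/autocorrelation-time
  estimator D = σ²/τ_A applied to the restrained coordinate of one
  umbrella window (Hummer's estimator).
* ``association_rate`` — the steady-state Smoluchowski flux solution
  with an absorbing inner boundary and an equilibrium outer reservoir;
  reduces to the Debye result 4πDξ_a N_A for free diffusion.
* ``mfpt_zwanzig`` — the mean first-passage time on a 1D landscape,
  τ = (1/D) ∫ dθ' e^{βF(θ')} ∫_a^{θ'} dθ'' e^{−βF(θ'')}, with a
  reflecting boundary at a.
* ``rotational_diffusion_wobbling`` — the wobbling-in-a-cone estimate of
  the rotational diffusion coefficient from the P₂ orientational
  autocorrelation time and the width of the entropy-corrected angular
  distribution (small-wobble closed form D = σ²/τ_P2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import AVOGADRO, DEFAULT_STATE, ThermoState
from .exceptions import (
    DomainError,
    FitError,
    InsufficientSamplingError,
)
from .profiles import FreeEnergyProfile1D
from .sampler import TimeSeries

__all__ = [
    "DiffusionProfile",
    "DiffusionEstimate",
    "RotationalEstimate",
    "RateResult",
    "estimate_window_diffusion",
    "build_diffusion_profile",
    "association_rate",
    "mfpt_zwanzig",
    "rotational_diffusion_wobbling",
    "flipping_rate",
    "integrated_autocorrelation_time",
]

#: (Å³/ns)·N_A expressed in M⁻¹ s⁻¹: 1e9 ns/s × 1e-27 L/Å³ × N_A.
_A3_PER_NS_TO_PER_M_S = 1.0e9 * 1.0e-27 * AVOGADRO


def integrated_autocorrelation_time(x: np.ndarray, dt: float) -> float:
    """τ_A = dt·(½ + Σ ρ_k), summing the ACF to its first negative value.

    The trapezoidal discretization makes τ_A converge to the continuous
    ACF integral (the exponential relaxation time for an OU process).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise DomainError("series too short for an autocorrelation time")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        raise DomainError("zero-variance series")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real / n
    rho = acov / acov[0]
    neg = np.nonzero(rho[1:] < 0.0)[0]
    cut = int(neg[0]) + 1 if neg.size else n
    return dt * (0.5 + float(np.sum(rho[1:cut])))


@dataclass(frozen=True)
class DiffusionEstimate:
    """D = σ²/τ_A for one umbrella window, with a block-bootstrap error."""

    d: float  # Å^2 / ns
    se: float
    sigma2: float  # Å^2
    tau: float  # ns
    xi_mean: float  # Å


def estimate_window_diffusion(
    ts: TimeSeries,
    burn_in: float = 0.1,
    n_boot: int = 32,
    n_blocks: int = 10,
    seed: int = 0,
) -> DiffusionEstimate:
    """Position-dependent diffusion from one restrained window.

    D = σ²/τ_A with σ² the sample variance of ξ and τ_A its integrated
    autocorrelation time; the standard error comes from a block
    bootstrap over contiguous trajectory blocks.
    """
    t = ts.burned_in(burn_in)
    if len(t) < 10_000:
        raise InsufficientSamplingError(
            f"only {len(t)} samples after burn-in; need at least 10^4"
        )
    dt = t.dt
    xi = t.xi
    tau = integrated_autocorrelation_time(xi, dt)
    n = len(xi)
    if tau > n * dt / 50.0:
        raise InsufficientSamplingError(
            f"autocorrelation time {tau:.3g} ns is not small against the "
            f"series length {n * dt:.3g} ns"
        )
    sigma2 = float(np.var(xi))
    d = sigma2 / tau
    # block bootstrap
    rng = np.random.default_rng(seed)
    blocks = np.array_split(xi, n_blocks)
    reps = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        xb = np.concatenate([blocks[j] for j in pick])
        reps.append(np.var(xb) / integrated_autocorrelation_time(xb, dt))
    return DiffusionEstimate(
        d=d,
        se=float(np.std(reps, ddof=1)),
        sigma2=sigma2,
        tau=tau,
        xi_mean=float(np.mean(xi)),
    )


@dataclass
class DiffusionProfile:
    """D(ξ) on window-mean nodes: linear interpolation, constant extrapolation."""

    nodes: np.ndarray  # Å
    values: np.ndarray  # Å^2/ns

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.nodes.ndim != 1 or self.nodes.shape != self.values.shape:
            raise DomainError("nodes and values must be 1D arrays of equal length")
        if len(self.nodes) < 2:
            raise DomainError("need at least two windows for a diffusion profile")
        if np.any(np.diff(self.nodes) <= 0):
            raise DomainError("diffusion nodes must be strictly increasing")
        if np.any(self.values <= 0):
            raise DomainError("all diffusion coefficients must be positive")

    def __call__(self, xi):
        return np.interp(xi, self.nodes, self.values)


def build_diffusion_profile(estimates, nodes=None) -> DiffusionProfile:
    """Assemble D(ξ) from per-window estimates.

    ``estimates`` may be a list of :class:`DiffusionEstimate` (nodes are
    their window-mean positions) or a plain array of D values with
    ``nodes`` given explicitly.  Nodes are sorted into increasing order.
    """
    if nodes is None:
        nodes = [e.xi_mean for e in estimates]
        values = [e.d for e in estimates]
    else:
        values = list(estimates)
    order = np.argsort(nodes)
    return DiffusionProfile(
        nodes=np.asarray(nodes)[order], values=np.asarray(values)[order]
    )


def association_rate(
    profile,
    diffusion,
    xi_a: float = 11.0,
    xi_b: float = 25.0,
    state: ThermoState = DEFAULT_STATE,
    jacobian_mode: str = "integrated",
    n_grid: int = 4001,
    rel_tol: float = 0.01,
) -> float:
    """Diffusion-controlled association rate k_on in M⁻¹ s⁻¹.

    Steady-state Smoluchowski flux with an absorbing boundary at ξ_a and
    an equilibrium reservoir at ξ_b:

        k_on = N_A · [∫_{ξa}^{ξb} e^{+βw(ξ)} / (4πξ² D(ξ)) dξ]⁻¹

    where w is the Jacobian-free PMF.  With ``jacobian_mode="integrated"``
    (the default) the input G is the angular-integrated profile whose
    plateau is flat, and the radial Jacobian is restored via
    w(ξ) = G(ξ) + (2/β) ln(ξ/ξ_b); with ``"radial"`` the input is used
    as w directly.  D is in Å²/ns; the quadrature is refined until the
    result is stable to ``rel_tol``.
    """
    if not xi_a < xi_b:
        raise DomainError("need xi_a < xi_b")
    if jacobian_mode not in ("integrated", "radial"):
        raise DomainError(f"unknown jacobian_mode {jacobian_mode!r}")

    if profile is None:
        gfun = lambda x: np.zeros_like(x)  # noqa: E731
    elif isinstance(profile, FreeEnergyProfile1D):
        # constant extrapolation; the plateau-zero convention makes G→0 outside
        def gfun(x):
            out = profile.interpolate(x)
            return np.where(x > profile.xi[-1], 0.0, out)
    elif callable(profile):
        gfun = profile
    else:
        raise DomainError("profile must be None, a FreeEnergyProfile1D or a callable")
    dfun = diffusion if callable(diffusion) else (lambda x: np.full_like(x, float(diffusion)))

    def integral(n):
        x = np.linspace(xi_a, xi_b, n)
        g = np.asarray(gfun(x), dtype=float)
        w = g + (2.0 / state.beta) * np.log(x / xi_b) if jacobian_mode == "integrated" else g
        d = np.asarray(dfun(x), dtype=float)
        if np.any(d <= 0):
            raise DomainError("diffusion must be positive on the integration range")
        integrand = np.exp(state.beta * w) / (4.0 * np.pi * x**2 * d)
        if not np.all(np.isfinite(integrand)):
            raise DomainError("diverging integrand (infinite free energy?)")
        return float(np.trapezoid(integrand, x))

    i1 = integral(n_grid)
    i2 = integral(2 * n_grid - 1)
    it = 0
    while abs(i2 - i1) > 0.2 * rel_tol * abs(i2) and it < 4:
        n_grid = 2 * n_grid - 1
        i1, i2 = i2, integral(2 * n_grid - 1)
        it += 1
    inv_a3_ns = 1.0 / i2  # Å^3 / ns
    return inv_a3_ns * _A3_PER_NS_TO_PER_M_S


def mfpt_zwanzig(
    potential,
    d_rot: float,
    theta0: float,
    theta1: float,
    reflecting_at: float = 0.0,
    state: ThermoState = DEFAULT_STATE,
    n_grid: int = 4001,
) -> float:
    """Mean first-passage time on a 1D angular landscape.

    τ = (1/D) ∫_{θ0}^{θ1} dθ' e^{βF(θ')} ∫_a^{θ'} dθ'' e^{−βF(θ'')}
    with a the reflecting boundary.  The mirrored geometry
    (a = 180°, θ0 > θ1) is handled by reflection.  ``d_rot`` is in
    deg²/s (or any deg²/time), so τ is in the matching time unit.
    """
    if d_rot <= 0:
        raise DomainError("d_rot must be positive")
    if theta0 == theta1:
        return 0.0
    a = reflecting_at
    base = potential if potential is not None else (lambda x: np.zeros_like(np.asarray(x, dtype=float)))
    if a <= theta0 < theta1:
        return _mfpt_integral(base, d_rot, theta0, theta1, a, state, n_grid)
    if a >= theta0 > theta1:
        # mirror about the reflecting boundary so the walk runs left-to-right
        f = lambda x: np.asarray(base(a - np.asarray(x)))  # noqa: E731
        return _mfpt_integral(f, d_rot, a - theta0, a - theta1, 0.0, state, n_grid)
    raise DomainError(
        "boundary ordering must satisfy a <= theta0 < theta1 (or mirrored)"
    )


def _mfpt_integral(f, d, x0, x1, a, state, n_grid):
    beta = state.beta
    grid = np.linspace(a, x1, n_grid)
    fg = np.asarray(f(grid), dtype=float)
    dx = grid[1] - grid[0]
    inner = np.concatenate(
        ([0.0], np.cumsum(0.5 * (np.exp(-beta * fg[1:]) + np.exp(-beta * fg[:-1])) * dx))
    )
    integrand = np.exp(beta * fg) * inner
    sel = grid >= x0
    # trapezoid over [x0, x1]
    tau = float(np.trapezoid(integrand[sel], grid[sel]))
    if grid[sel][0] > x0:  # partial first cell
        tau += float(
            0.5
            * (np.interp(x0, grid, integrand) + integrand[sel][0])
            * (grid[sel][0] - x0)
        )
    return tau / d


def flipping_rate(tau: float) -> float:
    """Interconversion rate 1/τ in s⁻¹ for τ in seconds."""
    if tau <= 0:
        raise DomainError("MFPT must be positive")
    return 1.0 / tau


@dataclass(frozen=True)
class RotationalEstimate:
    """Wobbling-in-a-cone rotational diffusion estimate."""

    d_rot: float  # deg^2 / time-unit of the input series
    sigma: float  # deg, width of the entropy-corrected angular distribution
    tau_p2: float  # time-units, integrated ACT of P2(cos θ)
    fit: dict


def rotational_diffusion_wobbling(
    ts: TimeSeries,
    state: ThermoState = DEFAULT_STATE,
    burn_in: float = 0.1,
    n_bins: int = 90,
) -> RotationalEstimate:
    """Rotational diffusion coefficient from a confined θ(t) series.

    (i) τ_P2 = integrated autocorrelation time of P₂(cos θ(t));
    (ii) the histogram of θ divided by sin θ (the entropy correction) is
    fitted by a Gaussian, giving the cone width σ in degrees;
    (iii) the small-wobble closed form D = σ²/τ_P2, corrected for the
    geometric sin θ term: the polar-angle walk relaxes in the effective
    well F − kT ln sin θ, whose extra curvature kT/sin²θ̄ shortens τ_P2
    relative to the cone width σ, so D is multiplied by
    1/(1 + σ_rad²/sin²θ̄).
    The time unit of ``ts`` fixes the unit of D (deg²/s for dt in s).
    """
    t = ts.burned_in(burn_in)
    theta = t.xi
    dt = t.dt
    rad = np.pi / 180.0
    p2 = 0.5 * (3.0 * np.cos(theta * rad) ** 2 - 1.0)
    tau_p2 = integrated_autocorrelation_time(p2, dt)

    hist, edges = np.histogram(theta, bins=n_bins, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    corrected = hist / np.sin(mids * rad)
    w = corrected / corrected.sum()
    mu0 = float(np.sum(w * mids))
    sig0 = float(np.sqrt(np.sum(w * (mids - mu0) ** 2)))

    def gauss(x, amp, mu, sig):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, pcov = curve_fit(
            gauss,
            mids,
            corrected,
            p0=(corrected.max(), mu0, max(sig0, 1.0)),
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise FitError(
            "Gaussian fit to the entropy-corrected angular distribution failed",
            diagnostics={"moment_mean": mu0, "moment_sigma": sig0},
        ) from err
    amp, mu, sigma = popt
    sigma = abs(float(sigma))
    resid = corrected - gauss(mids, *popt)
    rms = float(np.sqrt(np.mean(resid**2)) / corrected.max())
    if sigma <= 0 or rms > 0.25:
        raise FitError(
            "entropy-corrected angular distribution is not well described by a "
            "single Gaussian",
            diagnostics={"sigma": sigma, "relative_rms": rms},
        )
    sigma_rad = np.radians(sigma)
    geometric = 1.0 / (1.0 + sigma_rad**2 / np.sin(np.radians(mu)) ** 2)
    d_rot = sigma**2 / tau_p2 * geometric
    return RotationalEstimate(
        d_rot=d_rot,
        sigma=sigma,
        tau_p2=tau_p2,
        fit={"amplitude": float(amp), "mean": float(mu), "relative_rms": rms},
    )


@dataclass(frozen=True)
class RateResult:
    """Aggregated kinetic outputs with explicit units."""

    k_on: float  # M^-1 s^-1
    absorbing_boundary: float  # Å
    outer_boundary: float  # Å
    mfpt_ns: float  # ns
    flipping_rate_per_s: float  # s^-1

    def __post_init__(self):
        if self.k_on <= 0 or self.mfpt_ns <= 0:
            raise DomainError("rates and MFPT must be positive")
        if not math.isclose(
            self.flipping_rate_per_s, 1.0 / (self.mfpt_ns * 1e-9), rel_tol=1e-9
        ):
            raise DomainError("flipping rate must equal 1/MFPT")
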