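"""Synthetic biased-trajectory generation and stochastic oracles.

Overdamped (Brownian) Langevin dynamics on the reference surface under
harmonic umbrella biases stands in for the molecular-dynamics engine
that produced the original per-window trajectories.  Alongside the
umbrella sampler, this module provides bias-free oracle simulators used
to validate estimators:

* ``generate_ou`` — an exactly discretized Ornstein–Uhlenbeck process
  (known stationary variance 1/(βk) and relaxation time 1/(βkD)),
* ``generate_wobble`` — restricted rotational diffusion on the polar
  angle including the sin θ geometric weight,
* ``simulate_first_passage`` — replica Brownian dynamics between a
  reflecting and an absorbing boundary.

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .constants import DEFAULT_STATE, ThermoState
from .exceptions import DomainError, IntegrationError, SamplingGapError
from .landscape import ReferenceSurface

__all__ = [
    "UmbrellaWindow",
    "TimeSeries",
    "LadderConfig",
    "FirstPassageResult",
    "generate_window",
    "generate_ladder",
    "generate_ou",
    "generate_wobble",
    "simulate_first_passage",
    "harmonic_bias",
]

XI_DOMAIN = (3.5, 25.0)
THETA_DOMAIN = (0.0, 180.0)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic-bias window: w_i(ξ) = ½ k (ξ − ξ_i)²."""

    index: int
    bias_center: float  # Å
    force_constant: float  # kcal mol^-1 Å^-2
    n_steps: int = 1_600_000
    timestep: float = 0.002  # ns
    output_stride: int = 16

    def __post_init__(self):
        if self.force_constant <= 0:
            raise DomainError("force constant must be positive")
        if self.n_steps <= 0 or self.output_stride <= 0:
            raise DomainError("n_steps and output_stride must be positive")

    def bias(self, xi):
        return 0.5 * self.force_constant * (np.asarray(xi) - self.bias_center) ** 2


def harmonic_bias(center: float, force_constant: float):
    """The bias w(ξ) = ½k(ξ−c)² as a callable."""

    def w(xi):
        return 0.5 * force_constant * (np.asarray(xi) - center) ** 2

    return w


@dataclass
class TimeSeries:
    """A sampled trajectory of (ξ, θ) or of a single coordinate."""

    time: np.ndarray  # ns
    xi: np.ndarray
    theta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != self.xi.shape:
                raise DomainError("theta and xi must have the same length")
        if self.time.shape != self.xi.shape:
            raise DomainError("time and xi must have the same length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")

    def __len__(self):
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def burned_in(self, fraction: float = 0.1) -> "TimeSeries":
        n0 = int(len(self) * fraction)
        return replace(
            self,
            time=self.time[n0:],
            xi=self.xi[n0:],
            theta=None if self.theta is None else self.theta[n0:],
        )


@dataclass(frozen=True)
class LadderConfig:
    """The default 17-window umbrella ladder over 4.0 < ξ < 25.0 Å."""

    xi_min: float = 4.0
    xi_max: float = 25.0
    n_windows: int = 17
    force_constant: float = 2.0  # kcal mol^-1 Å^-2
    n_steps: int = 1_600_000
    timestep: float = 0.002  # ns
    output_stride: int = 16
    d_xi: float = 2.0  # Å^2/ns
    d_theta: float = 6000.0  # deg^2/ns
    base_seed: int = 19109

    def __post_init__(self):
        if self.n_windows < 2:
            raise DomainError("need at least 2 windows")
        if self.xi_max <= self.xi_min:
            raise DomainError("xi_max must exceed xi_min")

    def windows(self) -> list[UmbrellaWindow]:
        centers = np.linspace(self.xi_min, self.xi_max, self.n_windows)
        return [
            UmbrellaWindow(
                index=i,
                bias_center=float(c),
                force_constant=self.force_constant,
                n_steps=self.n_steps,
                timestep=self.timestep,
                output_stride=self.output_stride,
            )
            for i, c in enumerate(centers)
        ]

    def window_seeds(self) -> np.ndarray:
        rng = np.random.default_rng(self.base_seed)
        return rng.integers(0, 2**31 - 1, size=self.n_windows)


def _reflect(x, lo, hi):
    # two folds cover any step smaller than the domain width
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def _integrate_umbrella(
    surface: ReferenceSurface,
    state: ThermoState,
    centers: np.ndarray,
    force_constants: np.ndarray,
    d_xi: float,
    d_theta: float,
    dt: float,
    n_steps: int,
    stride: int,
    seeds: np.ndarray,
    xi_domain=XI_DOMAIN,
    theta_domain=THETA_DOMAIN,
    theta0: np.ndarray | None = None,
    metropolis: bool = True,
):
    """Brownian dynamics on (ξ, θ); all windows advanced in lockstep.

    The update is an Euler–Maruyama proposal, by default subjected to a
    Metropolis–Hastings correction (smart Monte Carlo / MALA), which
    makes the sampled stationary density exact at any stable timestep;
    proposals leaving the domain are rejected.  With
    ``metropolis=False`` the plain Euler–Maruyama update with reflecting
    boundaries is used (its density carries an O(dt) bias).

    Each window consumes noise from its own seeded generator, so a
    single-window run is bit-identical to the same window inside a
    ladder run.  Returns (times, xi, theta, acceptance_fraction).
    """
    if d_xi <= 0 or d_theta <= 0:
        raise DomainError("diffusion coefficients must be positive")
    if dt <= 0:
        raise DomainError("timestep must be positive")
    nw = len(centers)
    lo, hi = xi_domain
    tlo, thi = theta_domain
    rngs = [np.random.default_rng(int(s)) for s in np.asarray(seeds)]
    xi = np.clip(np.asarray(centers, dtype=float), lo + 1e-3, hi - 1e-3).copy()
    theta = (
        np.full(nw, 90.0) if theta0 is None else np.asarray(theta0, dtype=float).copy()
    )
    beta = state.beta
    c_xi = beta * d_xi * dt
    c_th = beta * d_theta * dt
    sig_xi = math.sqrt(2.0 * d_xi * dt)
    sig_th = math.sqrt(2.0 * d_theta * dt)
    q_xi = 1.0 / (4.0 * d_xi * dt)
    q_th = 1.0 / (4.0 * d_theta * dt)
    max_jump = 0.25 * (hi - lo)
    n_out = n_steps // stride
    out_xi = np.empty((n_out, nw))
    out_th = np.empty((n_out, nw))

    def energy_grad(x, t):
        u, gx, gt = surface.value_and_gradient(x, t)
        u = u + 0.5 * force_constants * (x - centers) ** 2
        gx = gx + force_constants * (x - centers)
        return u, gx, gt

    u, gx, gt = energy_grad(xi, theta)
    mx, mt = -c_xi * gx, -c_th * gt
    n_accept = 0
    chunk = 8192
    step = 0
    i_out = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = np.empty((m, nw, 2))
        unif = np.empty((m, nw))
        for j, rng in enumerate(rngs):
            noise[:, j, :] = rng.standard_normal((m, 2))
            unif[:, j] = rng.random(m)
        for i in range(m):
            dxi = mx + sig_xi * noise[i, :, 0]
            dth = mt + sig_th * noise[i, :, 1]
            bad = np.abs(dxi) > max_jump
            if np.any(bad):
                raise IntegrationError(
                    f"unstable step |dxi| > {max_jump:.2f} Å at step {step} "
                    f"(window index {int(np.argmax(bad))}); reduce timestep dt={dt} ns"
                )
            step += 1
            if metropolis:
                yx = xi + dxi
                yt = theta + dth
                inside = (yx > lo) & (yx < hi) & (yt > tlo) & (yt < thi)
                yx_s = np.where(inside, yx, xi)
                yt_s = np.where(inside, yt, theta)
                uy, gxy, gty = energy_grad(yx_s, yt_s)
                mxy, mty = -c_xi * gxy, -c_th * gty
                log_a = (
                    -beta * (uy - u)
                    + q_xi * ((yx_s - xi - mx) ** 2 - (xi - yx_s - mxy) ** 2)
                    + q_th * ((yt_s - theta - mt) ** 2 - (theta - yt_s - mty) ** 2)
                )
                accept = inside & (np.log(unif[i]) < log_a)
                n_accept += int(np.count_nonzero(accept))
                xi = np.where(accept, yx_s, xi)
                theta = np.where(accept, yt_s, theta)
                u = np.where(accept, uy, u)
                mx = np.where(accept, mxy, mx)
                mt = np.where(accept, mty, mt)
            else:
                xi = _reflect(xi + dxi, lo, hi)
                theta = _reflect(theta + dth, tlo, thi)
                u, gx, gt = energy_grad(xi, theta)
                mx, mt = -c_xi * gx, -c_th * gt
                n_accept += nw
            if step % stride == 0:
                out_xi[i_out] = xi
                out_th[i_out] = theta
                i_out += 1
    times = dt * stride * np.arange(1, n_out + 1)
    return times, out_xi, out_th, n_accept / (n_steps * nw)


def generate_window(
    surface: ReferenceSurface,
    window: UmbrellaWindow,
    state: ThermoState = DEFAULT_STATE,
    d_xi: float = 2.0,
    d_theta: float = 6000.0,
    seed: int = 0,
    theta0: float | None = None,
    metropolis: bool = True,
) -> TimeSeries:
    """Biased Brownian trajectory for a single umbrella window."""
    times, oxi, oth, acc = _integrate_umbrella(
        surface,
        state,
        centers=np.array([window.bias_center]),
        force_constants=np.array([window.force_constant]),
        d_xi=d_xi,
        d_theta=d_theta,
        dt=window.timestep,
        n_steps=window.n_steps,
        stride=window.output_stride,
        seeds=np.array([seed]),
        theta0=None if theta0 is None else np.array([theta0]),
        metropolis=metropolis,
    )
    return TimeSeries(
        time=times,
        xi=oxi[:, 0],
        theta=oth[:, 0],
        meta={
            "window": window.index,
            "bias_center": window.bias_center,
            "force_constant": window.force_constant,
            "seed": int(seed),
            "d_xi": d_xi,
            "d_theta": d_theta,
            "acceptance": acc,
            "surface": surface.fingerprint(),
        },
    )


def generate_ladder(
    surface: ReferenceSurface,
    config: LadderConfig = LadderConfig(),
    state: ThermoState = DEFAULT_STATE,
    check_overlap: bool = True,
) -> list[tuple[UmbrellaWindow, TimeSeries]]:
    """The full umbrella ladder; per-window seeds derive from the base seed.

    Adjacent-window ξ histograms are checked for shared support; a pair
    of windows with zero overlap raises :class:`SamplingGapError`.
    """
    windows = config.windows()
    seeds = config.window_seeds()
    centers = np.array([w.bias_center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    times, oxi, oth, acc = _integrate_umbrella(
        surface,
        state,
        centers=centers,
        force_constants=ks,
        d_xi=config.d_xi,
        d_theta=config.d_theta,
        dt=config.timestep,
        n_steps=config.n_steps,
        stride=config.output_stride,
        seeds=seeds,
    )
    out = []
    for j, w in enumerate(windows):
        ts = TimeSeries(
            time=times.copy(),
            xi=oxi[:, j].copy(),
            theta=oth[:, j].copy(),
            meta={
                "window": w.index,
                "bias_center": w.bias_center,
                "force_constant": w.force_constant,
                "seed": int(seeds[j]),
                "d_xi": config.d_xi,
                "d_theta": config.d_theta,
                "acceptance": acc,
                "surface": surface.fingerprint(),
            },
        )
        out.append((w, ts))
    if check_overlap:
        edges = np.linspace(XI_DOMAIN[0], XI_DOMAIN[1], 216)
        hists = [np.histogram(ts.xi, bins=edges)[0] > 0 for _, ts in out]
        for j in range(len(out) - 1):
            if not np.any(hists[j] & hists[j + 1]):
                raise SamplingGapError(
                    f"windows {j} and {j + 1} (centers "
                    f"{centers[j]:.2f}/{centers[j + 1]:.2f} Å) share no histogram bin"
                )
    return out


def generate_ou(
    force_constant: float,
    d: float,
    state: ThermoState = DEFAULT_STATE,
    n_steps: int = 100_000,
    dt: float = 0.01,
    seed: int = 0,
    mean: float = 0.0,
) -> TimeSeries:
    """Exact Ornstein–Uhlenbeck sampling (oracle for the diffusion estimator).

    The discretization uses the analytic transition density, so the
    stationary variance is exactly 1/(βk) and the relaxation time
    exactly 1/(βkD) regardless of dt.
    """
    if force_constant <= 0 or d <= 0 or dt <= 0:
        raise DomainError("force_constant, d and dt must be positive")
    beta = state.beta
    var = 1.0 / (beta * force_constant)
    tau = 1.0 / (beta * force_constant * d)
    a = math.exp(-dt / tau)
    s = math.sqrt(var * (1.0 - a * a))
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(n_steps)
    z = s * eta
    z[0] = math.sqrt(var) * eta[0]  # start in the stationary distribution
    x = lfilter([1.0], [1.0, -a], z) + mean
    t = dt * np.arange(1, n_steps + 1)
    return TimeSeries(
        time=t,
        xi=x,
        meta={"kind": "ou", "force_constant": force_constant, "d": d, "dt": dt,
              "seed": int(seed), "variance": var, "tau": tau},
    )


def generate_wobble(
    d_rot: float,
    angular_potential,
    n_steps: int = 100_000,
    dt: float = 1e-12,
    seed: int = 0,
    state: ThermoState = DEFAULT_STATE,
    theta0: float = 30.0,
    include_sin_weight: bool = True,
) -> TimeSeries:
    """Restricted rotational diffusion of the polar angle θ (degrees).

    Brownian dynamics with the geometric entropy term: the sampled
    density is ∝ sin θ · exp(−βF(θ)), which is what a polar angle of a
    wobbling axis obeys; an estimator that divides the histogram by
    sin θ recovers exp(−βF).  ``d_rot`` is in deg²/time-unit and ``dt``
    in the same time unit (seconds for the published value).
    """
    if d_rot <= 0 or dt <= 0:
        raise DomainError("d_rot and dt must be positive")
    beta = state.beta
    rad = math.pi / 180.0
    c = beta * d_rot * dt
    sig = math.sqrt(2.0 * d_rot * dt)
    h = 1e-4

    def dF(th):
        return (angular_potential(th + h) - angular_potential(th - h)) / (2 * h)

    rng = np.random.default_rng(seed)
    out = np.empty(n_steps)
    th = float(theta0)
    kT = state.kT
    max_jump = 45.0
    for i in range(n_steps):
        grad = dF(th)
        if include_sin_weight:
            # -d/dθ [kT ln sin θ], θ in degrees
            grad = grad - kT * rad / math.tan(th * rad)
        step = -c * grad + sig * rng.standard_normal()
        if abs(step) > max_jump:
            raise IntegrationError(
                f"unstable wobble step |dθ|={abs(step):.1f} deg at step {i}; "
                f"reduce dt={dt}"
            )
        th = th + step
        if th < 0.0:
            th = -th
        elif th > 180.0:
            th = 360.0 - th
        th = min(max(th, 1e-6), 180.0 - 1e-6)
        out[i] = th
    t = dt * np.arange(1, n_steps + 1)
    return TimeSeries(
        time=t,
        xi=out,
        meta={"kind": "wobble", "d_rot": d_rot, "dt": dt, "seed": int(seed)},
    )


@dataclass(frozen=True)
class FirstPassageResult:
    """Replica first-passage statistics."""

    mean: float
    se: float
    times: np.ndarray
    n_capped: int


def simulate_first_passage(
    potential,
    diffusion,
    start: float,
    absorbing_at: float,
    reflecting_at: float,
    n_replicas: int = 200,
    seed: int = 0,
    dt: float = 1e-3,
    max_steps: int = 20_000_000,
    state: ThermoState = DEFAULT_STATE,
) -> FirstPassageResult:
    """Mean first-passage time by replica Brownian dynamics.

    ``potential`` is a callable G(x) in kcal/mol (or None for a flat
    landscape); ``diffusion`` a constant or a callable D(x) in
    (length²/time).  Replicas are propagated in lockstep; the gradient
    is evaluated on a dense precomputed grid.  Replicas exceeding
    ``max_steps`` are counted in ``n_capped`` (never silently dropped);
    the mean is over completed replicas.
    """
    if absorbing_at == reflecting_at:
        raise DomainError("absorbing and reflecting boundaries must differ")
    lo, hi = sorted((absorbing_at, reflecting_at))
    if start == absorbing_at:
        return FirstPassageResult(0.0, 0.0, np.zeros(n_replicas), 0)
    if not (lo <= start <= hi):
        raise DomainError("start must lie between the boundaries")

    grid = np.linspace(lo, hi, 4001)
    if potential is None:
        force = np.zeros_like(grid)
    else:
        gvals = np.asarray([potential(x) for x in grid], dtype=float) \
            if not _vectorizable(potential, grid) else np.asarray(potential(grid), dtype=float)
        force = np.gradient(gvals, grid)
    if callable(diffusion):
        dvals = np.asarray(diffusion(grid), dtype=float)
    else:
        dvals = np.full_like(grid, float(diffusion))
    if np.any(dvals <= 0):
        raise DomainError("diffusion must be positive everywhere")
    ddvals = np.gradient(dvals, grid)

    beta = state.beta
    rng = np.random.default_rng(seed)
    x = np.full(n_replicas, float(start))
    t_abs = np.full(n_replicas, np.nan)
    alive = np.arange(n_replicas)
    absorb_low = absorbing_at < reflecting_at
    step_count = 0
    while alive.size and step_count < max_steps:
        d_here = np.interp(x, grid, dvals)
        drift = (-beta * d_here * np.interp(x, grid, force) + np.interp(x, grid, ddvals)) * dt
        x = x + drift + np.sqrt(2.0 * d_here * dt) * rng.standard_normal(alive.size)
        # reflecting boundary
        if absorb_low:
            over = x > hi
            x[over] = 2 * hi - x[over]
            hit = x <= lo
        else:
            under = x < lo
            x[under] = 2 * lo - x[under]
            hit = x >= hi
        step_count += 1
        if np.any(hit):
            t_abs[alive[hit]] = step_count * dt
            keep = ~hit
            x = x[keep]
            alive = alive[keep]
    n_capped = int(alive.size)
    done = np.isfinite(t_abs)
    times = t_abs[done]
    if times.size == 0:
        raise IntegrationError("no replica reached the absorbing boundary")
    mean = float(np.mean(times))
    se = float(np.std(times, ddof=1) / math.sqrt(times.size)) if times.size > 1 else 0.0
    return FirstPassageResult(mean=mean, se=se, times=times, n_capped=n_capped)


def _vectorizable(fn, grid):
    try:
        out = np.asarray(fn(grid[:2]))
        return out.shape == grid[:2].shape
    except Exception:
        return False
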