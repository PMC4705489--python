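"""End-to-end pipeline: generate → WHAM → thermo → kinetics → report.

``run_pipeline`` chains the stages on a calibrated (or freshly
calibrated) reference surface, persists every intermediate artifact
under the output directory, and returns a :class:`RunReport` whose
numeric fields are reproducible bit-for-bit from the configuration
alone.  Stochastic quantities carry block-bootstrap error estimates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .constants import ThermoState
from .exceptions import AmbdimerError, InsufficientSamplingError
from .kinetics import (
    association_rate,
    build_diffusion_profile,
    estimate_window_diffusion,
    flipping_rate,
    mfpt_zwanzig,
)
from .landscape import (
    DEFAULT_BOX_VOLUME,
    CalibrationTargets,
    ReferenceSurface,
    calibrate,
    load_default_surface,
    project_theta,
)
from .sampler import LadderConfig, generate_ladder
from .thermo import (
    dimer_fraction,
    dimerization_constant,
    onset_concentration,
)
from .wham import (
    basin_populations,
    locate_minima,
    orientation_stats,
    reweight_2d,
    solve_wham_1d,
)

log = logging.getLogger("ambdimer.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class WhamSettings:
    n_bins: int = 200
    xi_range: tuple = (4.0, 25.0)
    tol: float = 1e-7
    max_iter: int = 100_000
    equil_fraction: float = 0.1
    n_bootstrap: int = 12
    bootstrap_blocks: int = 10


@dataclass(frozen=True)
class KineticsSettings:
    absorbing_boundary: float = 11.0
    outer_boundary: float = 25.0
    d_rot: float = 3.8e12  # deg^2/s
    flip_theta0: float = 30.0
    flip_theta1: float = 150.0
    flip_reflecting: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run."""

    temperature: float = 300.0
    surface_source: str = "calibrate"  # "calibrate" | "fixture" | path to YAML
    ladder: LadderConfig = field(default_factory=LadderConfig)
    wham: WhamSettings = field(default_factory=WhamSettings)
    kinetics: KineticsSettings = field(default_factory=KineticsSettings)
    bound_radius: float = 11.0
    box_volume: float = DEFAULT_BOX_VOLUME
    onset_fraction: float = 0.10
    query_concentrations: tuple = (1.0e-6,)
    base_seed: int = 19109

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return unpack(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        ladder = d.pop("ladder", {})
        wham = d.pop("wham", {})
        kin = d.pop("kinetics", {})
        for key in ("xi_range",):
            if key in wham:
                wham[key] = tuple(wham[key])
        if "query_concentrations" in d:
            d["query_concentrations"] = tuple(d["query_concentrations"])
        return cls(
            ladder=LadderConfig(**ladder),
            wham=WhamSettings(**wham),
            kinetics=KineticsSettings(**kin),
            **d,
        )

    def fingerprint(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            base_seed=int(seed),
            ladder=dataclasses.replace(self.ladder, base_seed=int(seed)),
        )


@dataclass
class RunReport:
    """All headline quantities of one pipeline run (unit-tagged)."""

    delta_g_kcal_mol: float
    delta_g_se: float
    dimerization_constant: float
    onset_concentration_molar: float
    dimer_fractions: dict
    basin_populations: dict
    basin_populations_se: dict
    minima_positions_angstrom: tuple
    minima_depths_kcal_mol: tuple
    barrier_kcal_mol: float
    orientation: dict
    diffusion_table: list
    k_on_per_molar_s: float
    mfpt_flip_ns: float
    flipping_rate_per_s: float
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resolve_surface(config: PipelineConfig, state: ThermoState) -> ReferenceSurface:
    if config.surface_source == "fixture":
        return load_default_surface()
    if config.surface_source == "calibrate":
        targets = CalibrationTargets(
            bound_radius=config.bound_radius, box_volume=config.box_volume
        )
        return calibrate(targets, state=state)
    return ReferenceSurface.load(config.surface_source)


def _bootstrap_errors(series, windows, config, state, rng):
    """Block bootstrap over trajectory blocks → errors on ΔG°, pops, depths."""
    from .sampler import TimeSeries

    nb = config.wham.bootstrap_blocks
    dgs, pops_ii, depths = [], [], []
    for _ in range(config.wham.n_bootstrap):
        resampled = []
        for ts in series:
            blocks = np.array_split(np.arange(len(ts)), nb)
            pick = rng.integers(0, nb, nb)
            idx = np.concatenate([blocks[j] for j in pick])
            resampled.append(
                TimeSeries(time=ts.time[: len(idx)], xi=ts.xi[idx],
                           theta=None if ts.theta is None else ts.theta[idx],
                           meta=ts.meta)
            )
        try:
            prof_b, off_b = solve_wham_1d(
                resampled, windows, state,
                n_bins=config.wham.n_bins, xi_range=config.wham.xi_range,
                tol=config.wham.tol, max_iter=config.wham.max_iter,
                equil_fraction=config.wham.equil_fraction,
            )
            res_b = dimerization_constant(
                prof_b, state, bound_radius=config.bound_radius,
                box_volume=config.box_volume,
            )
            dgs.append(res_b.delta_g)
            surf_b = reweight_2d(
                resampled, windows, off_b, state,
                equil_fraction=config.wham.equil_fraction,
            )
            pops_ii.append(basin_populations(surf_b, state=state,
                                             bound_boundary=config.bound_radius))
            minima_b = locate_minima(prof_b)
            depths.append(np.mean(minima_b.values[:2]))
        except AmbdimerError:
            continue
    out = {}
    out["delta_g_se"] = float(np.std(dgs, ddof=1)) if len(dgs) > 1 else float("nan")
    if len(pops_ii) > 1:
        out["pop_se"] = {
            lab: float(np.std([p[lab] for p in pops_ii], ddof=1))
            for lab in pops_ii[0]
        }
    else:
        out["pop_se"] = {}
    out["depth_se"] = float(np.std(depths, ddof=1)) if len(depths) > 1 else float("nan")
    return out


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> RunReport:
    """Execute every stage in order and persist intermediate artifacts."""
    config = config or PipelineConfig()
    state = ThermoState(temperature=config.temperature)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "surface"
    try:
        t0 = time.time()
        surface = _resolve_surface(config, state)
        log.info("surface ready (fingerprint %s)", surface.fingerprint())
        if out is not None:
            surface.save(out / "surface.yaml")

        stage = "generate"
        ladder = generate_ladder(surface, config.ladder, state)
        windows = [w for w, _ in ladder]
        series = [ts for _, ts in ladder]
        log.info(
            "generated %d windows × %d samples in %.1f s",
            len(series), len(series[0]), time.time() - t0,
        )
        if out is not None:
            for w, ts in ladder:
                io.write_timeseries(out / f"window_{w.index:02d}.dat", ts)

        stage = "wham"
        profile, offsets = solve_wham_1d(
            series, windows, state,
            n_bins=config.wham.n_bins, xi_range=config.wham.xi_range,
            tol=config.wham.tol, max_iter=config.wham.max_iter,
            equil_fraction=config.wham.equil_fraction,
        )
        log.info("WHAM converged in %d iterations", offsets.n_iterations)
        surface2d = reweight_2d(
            series, windows, offsets, state,
            equil_fraction=config.wham.equil_fraction,
        )
        if out is not None:
            io.write_profile(out / "profile_1d.tsv", profile,
                             {"config": config.fingerprint()})
            io.write_offsets(out / "wham_offsets.tsv", offsets)
            io.write_surface(out / "surface_2d.tsv", surface2d)

        stage = "thermo"
        result = dimerization_constant(
            profile, state, bound_radius=config.bound_radius,
            box_volume=config.box_volume,
        )
        minima = locate_minima(profile)
        pops = basin_populations(surface2d, state=state,
                                 bound_boundary=config.bound_radius)
        orient = orientation_stats(surface2d, state,
                                   bound_boundary=config.bound_radius)
        onset = onset_concentration(result.delta_g, config.onset_fraction, state)
        fractions = {
            f"{c:g}": dimer_fraction(result.delta_g, c, state)
            for c in config.query_concentrations
        }
        log.info("ΔG° = %.2f kcal/mol, onset = %.3g M", result.delta_g, onset)

        stage = "bootstrap"
        rng = np.random.default_rng(config.base_seed + 1)
        errors = _bootstrap_errors(series, windows, config, state, rng)

        stage = "kinetics"
        estimates = []
        for ts in series:
            try:
                estimates.append(estimate_window_diffusion(ts))
            except InsufficientSamplingError as err:
                log.warning(
                    "window %s skipped in the diffusion profile: %s",
                    ts.meta.get("window"), err,
                )
        dprof = build_diffusion_profile(estimates)
        k_on = association_rate(
            profile, dprof,
            xi_a=config.kinetics.absorbing_boundary,
            xi_b=config.kinetics.outer_boundary,
            state=state,
        )
        ftheta = project_theta(surface, state, bound_boundary=config.bound_radius)
        tau_s = mfpt_zwanzig(
            ftheta.interpolate, config.kinetics.d_rot,
            config.kinetics.flip_theta0, config.kinetics.flip_theta1,
            reflecting_at=config.kinetics.flip_reflecting, state=state,
        )
        rate = flipping_rate(tau_s)
        log.info("k_on = %.3g /M/s, flipping MFPT = %.3g ns", k_on, tau_s * 1e9)

        report = RunReport(
            delta_g_kcal_mol=result.delta_g,
            delta_g_se=errors["delta_g_se"],
            dimerization_constant=result.k,
            onset_concentration_molar=onset,
            dimer_fractions=fractions,
            basin_populations=pops,
            basin_populations_se=errors["pop_se"],
            minima_positions_angstrom=tuple(sorted(minima.positions[:2])),
            minima_depths_kcal_mol=tuple(
                v for _, v in sorted(zip(minima.positions[:2], minima.values[:2]))
            ),
            barrier_kcal_mol=minima.barrier,
            orientation=dataclasses.asdict(orient),
            diffusion_table=[
                {"xi_mean_angstrom": e.xi_mean, "d_angstrom2_ns": e.d, "se": e.se}
                for e in estimates
            ],
            k_on_per_molar_s=k_on,
            mfpt_flip_ns=tau_s * 1e9,
            flipping_rate_per_s=rate,
            provenance={
                "package_version": __version__,
                "config": config.to_dict(),
                "config_fingerprint": config.fingerprint(),
                "surface_fingerprint": surface.fingerprint(),
                "convention": result.convention,
                "box_volume_angstrom3": config.box_volume,
                "standard_volume_angstrom3": result.standard_volume,
            },
        )
        if out is not None:
            io.write_report(out / "report.json", report.to_dict())
        return report
    except AmbdimerError as err:
        raise AmbdimerError(f"pipeline stage {stage!r} failed: {err}") from err
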