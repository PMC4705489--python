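"""Free-energy profile containers shared by the landscape and WHAM modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError


@dataclass
class FreeEnergyProfile1D:
    """A 1D free energy profile G(ξ) on a regular grid of bin centres.

    ``zero_convention`` records how the additive constant was fixed;
    the package uses ``"plateau-zero"`` (the unbound plateau, ξ ≥ 20 Å,
    averages to zero).
    """

    xi: np.ndarray
    g: np.ndarray
    counts: np.ndarray | None = None
    zero_convention: str = "plateau-zero"
    bin_width: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.xi.ndim != 1 or self.xi.shape != self.g.shape:
            raise DomainError("xi and g must be 1D arrays of equal length")
        if np.any(np.diff(self.xi) <= 0):
            raise DomainError("xi grid must be strictly increasing")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        if self.bin_width is None and len(self.xi) > 1:
            self.bin_width = float(np.median(np.diff(self.xi)))

    def interpolate(self, x):
        """Linear interpolation with edge-value (constant) extrapolation."""
        return np.interp(x, self.xi, self.g)

    def shifted(self, offset: float) -> "FreeEnergyProfile1D":
        return replace(self, g=self.g + offset)

    def plateau_shifted(self, plateau_from: float = 20.0) -> "FreeEnergyProfile1D":
        """Re-apply the plateau-zero convention.

        Shifts the profile so that the mean over bins with ξ >= ``plateau_from``
        is exactly zero.
        """
        mask = self.xi >= plateau_from
        if not np.any(mask):
            raise DomainError(
                f"profile does not reach the plateau region (xi >= {plateau_from})"
            )
        finite = mask & np.isfinite(self.g)
        if not np.any(finite):
            raise DomainError("no finite plateau bins to anchor the zero")
        out = replace(self, g=self.g - float(np.mean(self.g[finite])))
        out.zero_convention = "plateau-zero"
        return out


@dataclass
class FreeEnergySurface2D:
    """A 2D free energy surface G(ξ, angle) on a regular grid.

    ``mask`` is True for unsampled bins; those bins carry NaN in ``g``
    and are never imputed.  ``angle_tag`` names the second coordinate
    ("theta" for the inter-axis angle, "phi" for the secondary axis angle).
    """

    xi: np.ndarray
    angle: np.ndarray
    g: np.ndarray
    mask: np.ndarray
    angle_tag: str = "theta"
    counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.g.shape != (len(self.xi), len(self.angle)):
            raise DomainError("g must have shape (len(xi), len(angle))")
        if self.mask.shape != self.g.shape:
            raise DomainError("mask must have the same shape as g")
        if self.angle_tag not in ("theta", "phi"):
            raise DomainError(f"unknown angle_tag {self.angle_tag!r}")
        if np.any(np.isfinite(self.g[self.mask])):
            raise DomainError("masked bins must not carry finite values")


@dataclass(frozen=True)
class MinimaResult:
    """Local minima of a 1D profile and the barrier between the two deepest."""

    positions: tuple
    values: tuple
    barrier: float | None
    barrier_position: float | None = None
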