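"""Analytic potential surfaces used as ground truth for the estimators.

Every surface evaluates an energy in kcal/mol and its gradient at batches
of points in CV space (shape ``(n, ndim)``).  The stock families are a
harmonic well, a 1D quartic double well, and a 2D Gaussian-basin mixture
whose default parameters plant a three-state transporter-like landscape:
a deep basin, a metastable basin ~3 kcal/mol above it and a third basin
~2 kcal/mol up, separated by barriers of a few kcal/mol.  Those defaults
are fixtures with the right energy scale, not claims about any protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp

from . import units
from .errors import ValidationError

__all__ = [
    "PotentialSurface",
    "Harmonic",
    "DoubleWell1D",
    "GaussianBasinMixture",
    "three_basin_surface",
    "default_double_well",
    "boltzmann_bin_probabilities",
    "analytic_pmf_1d",
    "analytic_projected_pmf",
]


def _as_points(x, ndim: int) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if pts.shape[-1] != ndim:
        if ndim == 1 and pts.shape[0] == 1:
            pts = pts.T
        else:
            raise ValidationError(f"points must have {ndim} columns, got shape {pts.shape}")
    return pts


class PotentialSurface:
    """Base class: an analytic free-energy landscape over 1 or 2 CVs."""

    ndim: int

    def energy(self, x) -> np.ndarray:
        """Energy in kcal/mol at points of shape (n, ndim)."""
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:
        """Gradient in kcal/mol per CV unit, shape (n, ndim)."""
        raise NotImplementedError


@dataclass(frozen=True)
class Harmonic(PotentialSurface):
    """U = 1/2 sum_d k_d (x_d - c_d)^2 with k in kcal/mol/unit^2."""

    force_constants: tuple[float, ...] = (1.0,)
    centre: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        k = tuple(float(v) for v in np.atleast_1d(self.force_constants))
        c = self.centre
        c = tuple(0.0 for _ in k) if c is None else tuple(float(v) for v in np.atleast_1d(c))
        if len(c) != len(k):
            raise ValidationError("centre and force_constants length mismatch")
        object.__setattr__(self, "force_constants", k)
        object.__setattr__(self, "centre", c)

    @property
    def ndim(self) -> int:
        return len(self.force_constants)

    def energy(self, x) -> np.ndarray:
        pts = _as_points(x, self.ndim)
        d = pts - np.asarray(self.centre)
        return 0.5 * (d * d * np.asarray(self.force_constants)).sum(axis=1)

    def gradient(self, x) -> np.ndarray:
        pts = _as_points(x, self.ndim)
        return (pts - np.asarray(self.centre)) * np.asarray(self.force_constants)


@dataclass(frozen=True)
class DoubleWell1D(PotentialSurface):
    """Quartic double well U = h ((x-c)^2 - a^2)^2 / a^4.

    Minima at c +/- a with U = 0; central barrier of height ``h`` kcal/mol.
    """

    barrier: float = 3.0
    half_separation: float = 0.25  # nm
    centre: float = 0.6  # nm

    ndim = 1

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.half_separation <= 0:
            raise ValidationError("barrier and half_separation must be positive")

    def energy(self, x) -> np.ndarray:
        pts = _as_points(x, 1)[:, 0]
        a2 = self.half_separation**2
        return self.barrier * ((pts - self.centre) ** 2 - a2) ** 2 / a2**2

    def gradient(self, x) -> np.ndarray:
        pts = _as_points(x, 1)[:, 0]
        a2 = self.half_separation**2
        d = pts - self.centre
        g = self.barrier * 4.0 * d * (d * d - a2) / a2**2
        return g[:, None]

    @property
    def minima(self) -> tuple[float, float]:
        return (self.centre - self.half_separation, self.centre + self.half_separation)


@dataclass(frozen=True)
class GaussianBasinMixture(PotentialSurface):
    """Sum of inverted Gaussian wells plus a weak harmonic confinement.

    U(x) = -sum_i d_i exp(-|x - c_i|^2 / (2 s_i^2)) + 1/2 k_conf |x|^2

    The confinement keeps the unbiased Boltzmann density normalisable on
    the plateau outside the wells.
    """

    centres: tuple[tuple[float, ...], ...]
    depths: tuple[float, ...]
    widths: tuple[float, ...]
    confinement: float = 1.0  # kcal/mol/unit^2

    def __post_init__(self) -> None:
        centres = tuple(tuple(float(v) for v in c) for c in self.centres)
        depths = tuple(float(d) for d in self.depths)
        widths = tuple(float(w) for w in self.widths)
        if not centres:
            raise ValidationError("at least one basin required")
        if not (len(centres) == len(depths) == len(widths)):
            raise ValidationError("centres, depths, widths length mismatch")
        if any(d <= 0 for d in depths) or any(w <= 0 for w in widths):
            raise ValidationError("depths and widths must be positive")
        ndim = len(centres[0])
        if any(len(c) != ndim for c in centres):
            raise ValidationError("basin centres have inconsistent dimensionality")
        object.__setattr__(self, "centres", centres)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "widths", widths)

    @property
    def ndim(self) -> int:
        return len(self.centres[0])

    def energy(self, x) -> np.ndarray:
        pts = _as_points(x, self.ndim)
        u = 0.5 * self.confinement * (pts * pts).sum(axis=1)
        for c, d, w in zip(self.centres, self.depths, self.widths):
            r2 = ((pts - np.asarray(c)) ** 2).sum(axis=1)
            u = u - d * np.exp(-r2 / (2.0 * w * w))
        return u

    def gradient(self, x) -> np.ndarray:
        pts = _as_points(x, self.ndim)
        g = self.confinement * pts
        for c, d, w in zip(self.centres, self.depths, self.widths):
            diff = pts - np.asarray(c)
            r2 = (diff * diff).sum(axis=1)
            g = g + (d / (w * w)) * np.exp(-r2 / (2.0 * w * w))[:, None] * diff
        return g


def three_basin_surface() -> GaussianBasinMixture:
    """The stock two-CV transporter-like landscape.

    Three collinear basins along the first CV with planted relative free
    energies of about (0, +3, +2) kcal/mol and inter-basin barriers of
    about 3 and 2 kcal/mol above the higher of each basin pair.
    """
    return GaussianBasinMixture(
        centres=((-1.0, 0.0), (0.0, 0.0), (1.0, 0.0)),
        depths=(9.303, 5.705, 7.296),
        widths=(0.265, 0.301, 0.346),
        confinement=1.0,
    )


def default_double_well() -> DoubleWell1D:
    """Stock 1D double well: 3 kcal/mol barrier, minima at 0.35 and 0.85 nm."""
    return DoubleWell1D(barrier=3.0, half_separation=0.25, centre=0.6)


def boltzmann_bin_probabilities(
    surface: PotentialSurface,
    edges: np.ndarray,
    temperature: float = units.DEFAULT_TEMPERATURE,
    bias: "Callable[[np.ndarray], np.ndarray] | None" = None,
    oversample: int = 16,
) -> np.ndarray:
    """Exact (dense-quadrature) bin probabilities of exp(-beta (U + bias)).

    1D only; reference oracle for sampler histogram tests.
    """
    if surface.ndim != 1:
        raise ValidationError("boltzmann_bin_probabilities is 1D-only")
    edges = np.asarray(edges, dtype=float)
    b = units.beta(temperature)
    fine = np.linspace(edges[0], edges[-1], (edges.size - 1) * oversample + 1)
    mids = 0.5 * (fine[1:] + fine[:-1])
    u = surface.energy(mids[:, None])
    if bias is not None:
        u = u + bias(mids[:, None])
    logw = -b * u
    logw -= logsumexp(logw)
    w = np.exp(logw)
    return w.reshape(edges.size - 1, oversample).sum(axis=1)


def analytic_pmf_1d(
    surface: PotentialSurface,
    centres: np.ndarray,
    temperature: float = units.DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Exact 1D free-energy profile at bin centres, zeroed at its minimum.

    For a 1D surface this is just U(x) up to a constant; kept explicit so
    tests state their oracle."""
    vals = surface.energy(np.asarray(centres, dtype=float)[:, None])
    return vals - vals.min()


def analytic_projected_pmf(
    surface: PotentialSurface,
    x_centres: np.ndarray,
    temperature: float = units.DEFAULT_TEMPERATURE,
    y_limits: tuple[float, float] = (-4.0, 4.0),
    n_y: int = 2001,
) -> np.ndarray:
    """Marginal free energy along the first CV of a 2D surface.

    F(x) = -kT ln Int dy exp(-beta U(x, y)), computed by dense quadrature
    and zeroed at its minimum.  Oracle for the 2D -> 1D reweighting path.
    """
    if surface.ndim != 2:
        raise ValidationError("analytic_projected_pmf needs a 2D surface")
    kt = units.kt(temperature)
    y = np.linspace(y_limits[0], y_limits[1], n_y)
    dy = y[1] - y[0]
    out = np.empty(len(x_centres))
    for i, x in enumerate(np.asarray(x_centres, dtype=float)):
        pts = np.column_stack([np.full(n_y, x), y])
        u = surface.energy(pts)
        out[i] = -kt * (logsumexp(-u / kt) + np.log(dy))
    return out - out.min()
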