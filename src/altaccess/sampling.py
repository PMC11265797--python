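"""Overdamped Langevin (Brownian-dynamics) sampling on analytic surfaces.

This replaces the MD engine for synthetic-data purposes: the estimators
downstream only consume equilibrium distributions in CV space, so inertia
and kinetic fidelity are irrelevant.  The update rule is Euler-Maruyama,

    x <- x - grad(U + bias)/gamma * dt + sqrt(2 kT dt / gamma) * xi,

with gamma in 1/ps, energies in kcal/mol and an effective unit mass, so
the diffusion coefficient is D = kT/gamma.  The discretisation inflates
the sampled variance of a harmonic mode with stiffness k by a factor
1/(1 - k dt / (2 gamma)); choose dt so that k_max*dt/gamma stays below a
few percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import units
from .colvar import CVSeries
from .errors import StabilityError, ValidationError
from .surfaces import PotentialSurface

__all__ = [
    "BiasSpec",
    "LangevinParams",
    "UmbrellaWindow",
    "langevin_sample",
    "make_umbrella_campaign",
]


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias 1/2 sum_d k_d (x_d - c_d)^2.

    Force constants are stored in kcal/mol/(CV unit)^2; use
    :meth:`from_kj` for the kJ-based convention of window manifests.
    """

    centre: tuple[float, ...]
    force_constants: tuple[float, ...]  # kcal/mol/unit^2

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in np.atleast_1d(self.centre))
        k = tuple(float(v) for v in np.atleast_1d(self.force_constants))
        if len(c) != len(k):
            raise ValidationError("bias centre and force constants length mismatch")
        if any(v < 0 for v in k):
            raise ValidationError("force constants must be >= 0")
        object.__setattr__(self, "centre", c)
        object.__setattr__(self, "force_constants", k)

    @classmethod
    def from_kj(cls, centre, force_constants_kj) -> "BiasSpec":
        k = tuple(units.kj_to_kcal(float(v)) for v in np.atleast_1d(force_constants_kj))
        return cls(tuple(float(v) for v in np.atleast_1d(centre)), k)

    @property
    def ndim(self) -> int:
        return len(self.centre)

    def energy(self, x: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(x) - np.asarray(self.centre)
        return 0.5 * (d * d * np.asarray(self.force_constants)).sum(axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - np.asarray(self.centre)) * np.asarray(self.force_constants)


@dataclass(frozen=True)
class LangevinParams:
    timestep: float = 2e-5  # ps
    friction: float = 1.0  # 1/ps
    temperature: float = units.DEFAULT_TEMPERATURE  # K
    n_steps: int = 100_000
    stride: int = 50
    seed: int = 0
    burn_in_fraction: float = 0.1
    max_step: float = 1.0  # CV units; larger single steps abort the run

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.friction <= 0 or self.temperature <= 0:
            raise ValidationError("timestep, friction and temperature must be positive")
        if self.n_steps < 1 or self.stride < 1:
            raise ValidationError("n_steps and stride must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValidationError("burn_in_fraction must be in [0, 1)")


@dataclass(frozen=True)
class UmbrellaWindow:
    """Samples from one harmonically biased window."""

    samples: CVSeries
    bias: BiasSpec
    replicate: str = "rep0"
    tier: str = "tier0"

    def __post_init__(self) -> None:
        if self.samples.n_cvs != self.bias.ndim:
            raise ValidationError("sample dimensionality does not match bias dimensionality")


def _run_walkers(
    surface: PotentialSurface,
    biases: Sequence[BiasSpec | None],
    params: LangevinParams,
    starts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Propagate several walkers at once; returns (n_samples, n_walkers, ndim).

    All walkers share the surface and integrator settings but carry their
    own bias, which is what an umbrella campaign needs.
    """
    n_walkers, ndim = starts.shape
    dt = params.timestep
    mobility = dt / params.friction
    noise_scale = np.sqrt(2.0 * units.kt(params.temperature) * mobility)
    centres = np.array(
        [b.centre if b is not None else [0.0] * ndim for b in biases], dtype=float
    )
    ks = np.array(
        [b.force_constants if b is not None else [0.0] * ndim for b in biases],
        dtype=float,
    )
    x = starts.copy()
    n_burn = int(params.burn_in_fraction * params.n_steps)
    n_keep = (params.n_steps - n_burn) // params.stride
    if n_keep < 1:
        raise ValidationError("n_steps too small for the requested stride and burn-in")
    out = np.empty((n_keep, n_walkers, ndim))
    isample = 0
    for step in range(params.n_steps):
        grad = surface.gradient(x) + (x - centres) * ks
        dx = -grad * mobility + noise_scale * rng.standard_normal(x.shape)
        if np.abs(dx).max() > params.max_step:
            raise StabilityError(
                "divergent integrator step; reduce the timestep or increase friction"
            )
        x = x + dx
        if step >= n_burn and (step - n_burn) % params.stride == params.stride - 1:
            out[isample] = x
            isample += 1
    return out[:isample]


def langevin_sample(
    surface: PotentialSurface,
    bias: BiasSpec | None,
    params: LangevinParams,
    start,
    labels: Sequence[str] | None = None,
) -> CVSeries:
    """Sample the surface (optionally under a harmonic bias).

    Returns strided post-burn-in samples as a CVSeries whose times are the
    simulation times (ps) at which samples were taken.  Reproducible from
    ``params.seed``.
    """
    start_arr = np.atleast_1d(np.asarray(start, dtype=float))[None, :]
    if start_arr.shape[1] != surface.ndim:
        raise ValidationError("start point dimensionality mismatch")
    if bias is not None and bias.ndim != surface.ndim:
        raise ValidationError("bias dimensionality mismatch")
    rng = np.random.default_rng(params.seed)
    traj = _run_walkers(surface, [bias], params, start_arr, rng)[:, 0, :]
    if labels is None:
        labels = tuple(f"cv{i + 1}" for i in range(surface.ndim))
    times = (np.arange(traj.shape[0]) + 1) * params.stride * params.timestep
    return CVSeries(tuple(labels), times, traj)


def make_umbrella_campaign(
    surface: PotentialSurface,
    centres: Sequence,
    tiers: Sequence[Sequence[float]],
    params: LangevinParams,
    n_replicates: int = 1,
) -> list[UmbrellaWindow]:
    """Run a biased window at every (centre, force-constant tier, replicate).

    ``tiers`` holds one per-dimension force-constant vector (kcal/mol/unit^2)
    per tier; pooling two tiers per centre mirrors designs that combine a
    soft tier for broad basins with a stiff tier for barrier regions.
    24 centres x 2 tiers x 3 replicates gives the canonical 144 windows.
    All windows are propagated simultaneously as independent walkers.
    """
    centre_arr = np.atleast_2d(np.asarray(centres, dtype=float))
    if surface.ndim == 1 and centre_arr.shape[0] == 1 and centre_arr.shape[1] > 1:
        centre_arr = centre_arr.T
    if centre_arr.shape[0] == 0:
        raise ValidationError("centres must be nonempty")
    if centre_arr.shape[1] != surface.ndim:
        raise ValidationError("centre dimensionality does not match the surface")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    biases: list[BiasSpec] = []
    meta: list[tuple[str, str]] = []
    for irep in range(n_replicates):
        for itier, k in enumerate(tiers):
            for c in centre_arr:
                biases.append(BiasSpec(tuple(c), tuple(float(v) for v in np.atleast_1d(k))))
                meta.append((f"rep{irep}", f"tier{itier}"))
    rng = np.random.default_rng(params.seed)
    starts = np.array([b.centre for b in biases], dtype=float)
    traj = _run_walkers(surface, biases, params, starts, rng)
    labels = tuple(f"cv{i + 1}" for i in range(surface.ndim))
    times = (np.arange(traj.shape[0]) + 1) * params.stride * params.timestep
    windows = []
    for iw, (bias, (rep, tier)) in enumerate(zip(biases, meta)):
        series = CVSeries(labels, times, traj[:, iw, :])
        windows.append(UmbrellaWindow(series, bias, replicate=rep, tier=tier))
    return windows
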