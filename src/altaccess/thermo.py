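"""Free-energy estimators and thermodynamic-cycle assembly.

Sign conventions, stated once:

==========================  ================================================
Quantity                    Convention
==========================  ================================================
Leg dG                      Work direction of the leg as labelled; complex
                            legs are annihilation (restrain, then decouple
                            coulomb/vdw) in the bound state, ligand legs are
                            annihilation of the free ligand in solution.
Boresch term                dG of *releasing* the orientational restraints
                            of a noninteracting ligand into the standard-
                            state volume V0 (negative for stiff restraints).
Binding affinity            Reported as a positive magnitude: affinity =
                            dG_unbind = sum(complex legs) + boresch_release
                            - sum(ligand legs); larger means tighter binding.
Protonation edge            dG_prot(pH) = RT ln(10) (pH - pKa): protonation
                            is favourable (negative) below the pKa.
Cycle residual              Oriented sum of edge dGs around the loop; SD is
                            the root-sum-square of edge SDs.
==========================  ================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from . import units
from .errors import OverlapError, ValidationError
from .synth import WorkSamples
from .titration import PkaEstimate

__all__ = [
    "AlchemicalLeg",
    "BoreschSpec",
    "FreeEnergyEdge",
    "ThermodynamicCycle",
    "bar_estimate",
    "ti_estimate",
    "boresch_analytic",
    "assemble_abfe",
    "cycle_closure",
    "protonation_edge_from_pka",
]


@dataclass(frozen=True)
class AlchemicalLeg:
    """One alchemical transformation leg with its estimate."""

    label: str
    dg: float  # kcal/mol
    sd: float
    lambdas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("leg SD must be >= 0")
        if self.lambdas is not None:
            lam = tuple(float(v) for v in self.lambdas)
            if lam[0] != 0.0 or lam[-1] != 1.0 or np.any(np.diff(lam) <= 0):
                raise ValidationError(
                    "lambda schedule must start at 0, end at 1 and be strictly increasing"
                )
            object.__setattr__(self, "lambdas", lam)


@dataclass(frozen=True)
class BoreschSpec:
    """One distance, two angles and three dihedrals restraining a ligand.

    Force constants come in kJ/mol/nm^2 (distance) and kJ/mol/rad^2
    (angles/dihedrals), matching window-manifest conventions, and are
    converted internally.
    """

    r0: float  # nm
    theta_a: float  # rad
    theta_b: float  # rad
    k_r: float  # kJ/mol/nm^2
    k_theta_a: float  # kJ/mol/rad^2
    k_theta_b: float
    k_phi_a: float
    k_phi_b: float
    k_phi_c: float
    temperature: float = units.DEFAULT_TEMPERATURE
    standard_volume: float = units.STANDARD_VOLUME_NM3  # nm^3 per molecule

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValidationError("r0 must be positive")
        if not (0.0 < self.theta_a < math.pi) or not (0.0 < self.theta_b < math.pi):
            raise ValidationError("reference angles must lie strictly inside (0, pi)")
        for name in ("k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def force_constants_kcal(self) -> tuple[float, ...]:
        return tuple(
            units.kj_to_kcal(getattr(self, name))
            for name in ("k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c")
        )


@dataclass(frozen=True)
class FreeEnergyEdge:
    """A signed free-energy difference between two named states."""

    label: str
    dg: float  # kcal/mol
    sd: float
    state_from: str
    state_to: str
    orientation: int = +1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("edge SD must be >= 0")
        if self.orientation not in (+1, -1):
            raise ValidationError("orientation must be +1 or -1")

    @property
    def oriented_tail(self) -> str:
        return self.state_from if self.orientation == +1 else self.state_to

    @property
    def oriented_head(self) -> str:
        return self.state_to if self.orientation == +1 else self.state_from


@dataclass(frozen=True)
class ThermodynamicCycle:
    """Ordered edges traversing a closed loop of states."""

    edges: tuple[FreeEnergyEdge, ...]

    def __post_init__(self) -> None:
        edges = tuple(self.edges)
        if len(edges) < 2:
            raise ValidationError("a cycle needs at least two edges")
        object.__setattr__(self, "edges", edges)
        for prev, nxt in zip(edges, edges[1:]):
            if prev.oriented_head != nxt.oriented_tail:
                raise ValidationError(
                    f"open loop: edge {prev.label!r} ends at {prev.oriented_head!r} "
                    f"but edge {nxt.label!r} starts at {nxt.oriented_tail!r}"
                )
        if edges[-1].oriented_head != edges[0].oriented_tail:
            raise ValidationError(
                f"open loop: cycle ends at {edges[-1].oriented_head!r}, "
                f"started at {edges[0].oriented_tail!r}"
            )

    def reversed(self) -> "ThermodynamicCycle":
        flipped = tuple(
            FreeEnergyEdge(e.label, e.dg, e.sd, e.state_from, e.state_to,
                           -e.orientation)
            for e in reversed(self.edges)
        )
        return ThermodynamicCycle(flipped)


def bar_estimate(samples: WorkSamples) -> tuple[float, float]:
    """Bennett acceptance ratio from forward/reverse work samples.

    Solves the self-consistent Bennett condition; the SD is the standard
    asymptotic BAR variance.  With only one work direction available the
    estimator falls back to exponential averaging (with a warning), whose
    SD comes from the delta method.
    """
    import warnings

    b = units.beta(samples.temperature)
    w_f, w_r = samples.forward, samples.reverse
    if w_f.size == 0 or w_r.size == 0:
        warnings.warn(
            "only one work direction available; falling back to exponential averaging",
            stacklevel=2,
        )
        work, sign = (w_f, 1.0) if w_f.size else (w_r, -1.0)
        x = -b * work
        log_mean = logsumexp(x) - np.log(work.size)
        dg = sign * (-log_mean / b)
        weights = np.exp(x - x.max())
        rel_var = weights.var() / (weights.mean() ** 2 * work.size)
        return float(dg), float(np.sqrt(rel_var) / b)

    n_f, n_r = w_f.size, w_r.size
    m = math.log(n_f / n_r)

    def bennett_residual(dg: float) -> float:
        lhs = expit(-(m + b * (w_f - dg))).sum()
        rhs = expit(-(-m + b * (w_r + dg))).sum()
        return lhs - rhs

    span = float(np.concatenate([np.abs(w_f), np.abs(w_r)]).max()) + 10.0 / b
    lo, hi = -span, span
    if bennett_residual(lo) * bennett_residual(hi) > 0:
        raise OverlapError("work distributions do not overlap; BAR has no solution")
    dg = brentq(bennett_residual, lo, hi, xtol=1e-12)

    # Bennett variance: fluctuations of the Fermi weights in each ensemble
    f_f = expit(-(m + b * (w_f - dg)))
    f_r = expit(-(-m + b * (w_r + dg)))
    if f_f.mean() == 0 or f_r.mean() == 0:
        raise OverlapError("degenerate Fermi weights; no overlap")
    var_beta_dg = (
        (f_f**2).mean() / (n_f * f_f.mean() ** 2)
        - 1.0 / n_f
        + (f_r**2).mean() / (n_r * f_r.mean() ** 2)
        - 1.0 / n_r
    )
    sd = math.sqrt(max(var_beta_dg, 0.0)) / b
    return float(dg), float(sd)


def ti_estimate(
    lambdas: Sequence[float],
    dhdl_means: Sequence[float],
    dhdl_sems: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Thermodynamic integration by trapezoidal quadrature.

    dG = Int_0^1 <dH/dlambda> dlambda; the SD propagates the per-lambda
    SEMs through the trapezoid weights.
    """
    lam = np.asarray(lambdas, dtype=float)
    means = np.asarray(dhdl_means, dtype=float)
    if lam.size != means.size or lam.size < 2:
        raise ValidationError("lambda schedule and dH/dlambda means must match, n >= 2")
    if np.any(np.diff(lam) <= 0):
        raise ValidationError("lambda values must be strictly increasing")
    if not (np.isclose(lam[0], 0.0) and np.isclose(lam[-1], 1.0)):
        raise ValidationError("lambda schedule must span [0, 1]; missing end point")
    dg = float(np.trapezoid(means, lam))
    if dhdl_sems is None:
        return dg, 0.0
    sems = np.asarray(dhdl_sems, dtype=float)
    if sems.size != lam.size:
        raise ValidationError("SEM count does not match lambda count")
    weights = np.zeros_like(lam)
    weights[:-1] += 0.5 * np.diff(lam)
    weights[1:] += 0.5 * np.diff(lam)
    return dg, float(np.sqrt(((weights * sems) ** 2).sum()))


def boresch_analytic(spec: BoreschSpec) -> float:
    """Analytic standard-state term for six harmonic Boresch restraints.

    dG of releasing a restrained, noninteracting ligand into the standard
    volume:

        dG = -kT ln[ 8 pi^2 V0 sqrt(k_r k_tA k_tB k_pA k_pB k_pC)
                     / (r0^2 sin(tA) sin(tB) (2 pi kT)^3) ]

    valid in the stiff-restraint (Gaussian) regime.  Doubling every force
    constant shifts the result by -3 kT ln 2 (six constants, each entering
    as sqrt(k)).
    """
    kt = units.kt(spec.temperature)
    ks = spec.force_constants_kcal()
    sin_a, sin_b = math.sin(spec.theta_a), math.sin(spec.theta_b)
    numerator = 8.0 * math.pi**2 * spec.standard_volume * math.sqrt(math.prod(ks))
    denominator = spec.r0**2 * sin_a * sin_b * (2.0 * math.pi * kt) ** 3
    return -kt * math.log(numerator / denominator)


def assemble_abfe(
    complex_legs: Sequence[AlchemicalLeg],
    ligand_legs: Sequence[AlchemicalLeg],
    boresch_release: float,
) -> tuple[float, float]:
    """Assemble a double-decoupling binding affinity (positive magnitude).

    affinity = sum(complex legs) + boresch_release - sum(ligand legs);
    SD is the root-sum-square of the leg SDs (the analytic Boresch term is
    exact).  See the module sign table.
    """
    if not complex_legs:
        raise ValidationError("missing complex-side legs")
    if not ligand_legs:
        raise ValidationError("missing ligand-side legs")
    affinity = (
        sum(l.dg for l in complex_legs)
        + boresch_release
        - sum(l.dg for l in ligand_legs)
    )
    sd = math.sqrt(sum(l.sd**2 for l in (*complex_legs, *ligand_legs)))
    return float(affinity), float(sd)


def cycle_closure(cycle: ThermodynamicCycle) -> tuple[float, float]:
    """Oriented sum of edge dGs around the loop and its propagated SD.

    The residual of a thermodynamically consistent cycle is zero within
    the root-sum-square of the edge SDs.
    """
    residual = sum(e.orientation * e.dg for e in cycle.edges)
    sd = math.sqrt(sum(e.sd**2 for e in cycle.edges))
    return float(residual), float(sd)


def protonation_edge_from_pka(
    estimate: PkaEstimate | float,
    ph: float,
    sd: float = 0.0,
    temperature: float = units.DEFAULT_TEMPERATURE,
    state_from: str = "deprotonated",
    state_to: str = "protonated",
    label: str | None = None,
) -> FreeEnergyEdge:
    """Protonation free-energy edge at a given pH from a pKa estimate.

    dG_prot = RT ln(10) (pH - pKa); the pKa SD scales by RT ln(10).
    """
    pka = estimate.pka if isinstance(estimate, PkaEstimate) else float(estimate)
    factor = units.rt_ln10(temperature)
    return FreeEnergyEdge(
        label=label or f"protonation@pH{ph:g}",
        dg=factor * (ph - pka),
        sd=factor * sd,
        state_from=state_from,
        state_to=state_to,
    )
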