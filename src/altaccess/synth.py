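"""Synthetic generators for the non-surface inputs of the pipeline.

Everything here produces data with known ground truth: two-state Markov
protonation traces with a prescribed stationary titration curve and
autocorrelation time, replicate path ensembles that differ along a
planted orthogonal direction, and Gaussian forward/reverse work samples
that satisfy the Crooks fluctuation relation around a planted free-energy
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import units
from .errors import ValidationError
from .titration import ProtonationSeries

__all__ = [
    "PathEnsembleSet",
    "WorkSamples",
    "make_titration_data",
    "make_path_ensembles",
    "make_alchemical_samples",
]


@dataclass(frozen=True)
class PathEnsembleSet:
    """Replicate transition paths: frames[n, i] is the coordinate vector of
    window n in replicate i.  The planted inter-replicate direction, when
    known, is stored for recovery tests."""

    frames: np.ndarray  # (n_windows, n_replicates, dim)
    ground_truth_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValidationError("frames must have shape (n_windows, n_replicates, dim)")
        object.__setattr__(self, "frames", frames)
        if self.ground_truth_direction is not None:
            d = np.asarray(self.ground_truth_direction, dtype=float)
            if d.shape != (frames.shape[2],):
                raise ValidationError("ground-truth direction dimensionality mismatch")
            object.__setattr__(self, "ground_truth_direction", d / np.linalg.norm(d))

    @property
    def n_windows(self) -> int:
        return self.frames.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.frames.shape[1]

    def pooled_frames(self) -> np.ndarray:
        """All frames stacked as (n_windows * n_replicates, dim)."""
        return self.frames.reshape(-1, self.frames.shape[2])


@dataclass(frozen=True)
class WorkSamples:
    """Forward and reverse work values (kcal/mol) for one alchemical interval."""

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = units.DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        fwd = np.atleast_1d(np.asarray(self.forward, dtype=float))
        rev = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if fwd.size == 0 and rev.size == 0:
            raise ValidationError("at least one work direction must be nonempty")
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)


def make_titration_data(
    true_pka: float,
    hill: float = 1.0,
    ph_values: Sequence[float] = tuple(range(8)),
    n_frames: int = 100_000,
    correlation_time: float = 10.0,
    seed: int = 0,
    residue: str = "E56",
    frame_period_ns: float = 1.0,
) -> ProtonationSeries:
    """Two-state Markov protonation traces across a pH ladder.

    Each pH replica is an independent two-state chain whose stationary
    deprotonated fraction is 1/(1 + 10^(hill (pKa - pH))) and whose state
    autocorrelation decays as exp(-lag / correlation_time) (in frames).
    The chain starts from its stationary distribution, so traces are
    stationary from frame zero.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be positive")
    if correlation_time <= 0:
        raise ValidationError("correlation_time must be positive")
    if correlation_time >= n_frames:
        warnings.warn(
            "correlation_time is not shorter than the trace; titration fits "
            "on this data will be unstable",
            stacklevel=2,
        )
    ph = np.asarray(ph_values, dtype=float)
    pi_deprot = 1.0 / (1.0 + 10.0 ** (hill * (true_pka - ph)))
    lam = np.exp(-1.0 / correlation_time)  # second eigenvalue of the chain
    rng = np.random.default_rng(seed)
    # Transition probabilities with stationary pi and eigenvalue lam:
    # p(prot -> deprot) = (1 - lam) pi_deprot, p(deprot -> prot) = (1 - lam) pi_prot
    traces = np.empty((ph.size, n_frames), dtype=np.int8)
    state_deprot = rng.random(ph.size) < pi_deprot
    u = rng.random((n_frames, ph.size))
    p_to_deprot = (1.0 - lam) * pi_deprot
    p_to_prot = (1.0 - lam) * (1.0 - pi_deprot)
    for t in range(n_frames):
        flip = np.where(state_deprot, u[t] < p_to_prot, u[t] < p_to_deprot)
        state_deprot = state_deprot ^ flip
        traces[:, t] = (~state_deprot).astype(np.int8)  # 1 = protonated
    return ProtonationSeries(residue, tuple(ph), traces, frame_period_ns)


def make_path_ensembles(
    n_reps: int = 3,
    n_windows: int = 24,
    base_path: np.ndarray | None = None,
    separation_direction: np.ndarray | None = None,
    separation_scale: float = 0.5,
    noise: float = 0.05,
    seed: int = 0,
    dim: int = 48,
) -> PathEnsembleSet:
    """Replicate paths differing along a planted orthogonal direction.

    Replicate i is base_path + offset_i * direction + Gaussian noise, with
    distinct, evenly spread offsets.  Defaults plant a smooth base path
    whose dominant variation lies along the first few coordinates and a
    separation direction orthogonal to it, which is the structure the
    second-CV optimisation is meant to discover.
    """
    if n_reps < 2:
        raise ValidationError("need at least two replicates")
    if base_path is None:
        s = np.linspace(-1.0, 1.0, n_windows)
        base_path = np.zeros((n_windows, dim))
        base_path[:, 0] = 2.0 * s  # dominant gating-like motion
        base_path[:, 1] = 0.6 * np.sin(np.pi * s)
        base_path[:, 2] = 0.3 * np.cos(2.0 * np.pi * s)
    base_path = np.asarray(base_path, dtype=float)
    if base_path.ndim != 2:
        raise ValidationError("base_path must be (n_windows, dim)")
    n_windows, dim = base_path.shape
    if separation_direction is None:
        separation_direction = np.zeros(dim)
        separation_direction[5] = 1.0
    direction = np.asarray(separation_direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValidationError("separation direction must be nonzero")
    direction = direction / norm
    offsets = np.linspace(-1.0, 1.0, n_reps) * separation_scale
    rng = np.random.default_rng(seed)
    frames = (
        base_path[:, None, :]
        + offsets[None, :, None] * direction[None, None, :]
        + noise * rng.standard_normal((n_windows, n_reps, dim))
    )
    return PathEnsembleSet(frames, ground_truth_direction=direction)


def make_alchemical_samples(
    dg_true: float,
    sigma_w: float,
    n: int,
    seed: int = 0,
    temperature: float = units.DEFAULT_TEMPERATURE,
) -> WorkSamples:
    """Gaussian work distributions consistent with the Crooks relation.

    Forward work ~ N(dG + beta sigma^2 / 2, sigma^2) and reverse work
    ~ N(-dG + beta sigma^2 / 2, sigma^2), so that P_F(W) / P_R(-W)
    = exp(beta (W - dG)) holds exactly with the planted dG (kcal/mol).
    As sigma -> 0 every work value equals the planted dG.
    """
    if n < 2:
        raise ValidationError("need at least two work samples per direction")
    if sigma_w < 0:
        raise ValidationError("sigma_w must be >= 0")
    b = units.beta(temperature)
    rng = np.random.default_rng(seed)
    dissipation = 0.5 * b * sigma_w**2
    fwd = dg_true + dissipation + sigma_w * rng.standard_normal(n)
    rev = -dg_true + dissipation + sigma_w * rng.standard_normal(n)
    return WorkSamples(fwd, rev, temperature=temperature)
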