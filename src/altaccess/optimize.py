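"""Optimisation of the second collective variable.

Replicate transition paths that disagree do so along directions orthogonal
to the main gating motion (PC 1).  To expose that disagreement as a
sampling coordinate, an entropy-like separation metric

    M = 2 / (Nrep (Nrep - 1)) * sum_{i<j} sum_n log d^2(n, i, j)

is maximised by differential evolution over linear combinations of
PCs 2..16, where d(n, i, j) is the separation of the frames of window n
in replicates i and j evaluated along the candidate combination.  Two
readings of that separation are supported (see ``mode``):

- ``projection`` (default): d^2 = (v . (X(n,i) - X(n,j)))^2 with
  v = sum_k w_k PC_k — the difference projected onto the single combined
  direction;
- ``per_pc``: d^2 = sum_k w_k^2 (p_k(n,i) - p_k(n,j))^2 — a weighted sum
  of squared per-PC differences.

Scaling v rescales every d^2 by the same factor, which only shifts the
metric by a constant (log identity), so the search is effectively over
directions; weights are normalised after optimisation and the sign is
canonicalised so the largest-magnitude weight is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from .errors import ValidationError
from .pca import PCBasis, WeightVector
from .synth import PathEnsembleSet

__all__ = ["path_separation_metric", "optimize_pc2", "OptimizeResult"]

_LOG_FLOOR = 1e-12  # floor on d^2 before the log; identical frames otherwise give -inf

N_COMBINED_PCS = 15  # PCs 2..16


def _pc_diffs(paths: PathEnsembleSet, basis: PCBasis, first_pc: int, n_pcs: int) -> np.ndarray:
    """Per-PC projected frame differences, shape (n_pairs, n_windows, n_pcs)."""
    lo = first_pc - 1
    comps = basis.components[lo : lo + n_pcs]
    proj = np.einsum("nrd,kd->nrk", paths.frames - basis.mean, comps)
    n_rep = paths.n_replicates
    pairs = [(i, j) for i in range(n_rep) for j in range(i + 1, n_rep)]
    return np.stack([proj[:, i, :] - proj[:, j, :] for i, j in pairs])


def path_separation_metric(
    paths: PathEnsembleSet,
    w: WeightVector,
    basis: PCBasis,
    mode: str = "projection",
    eps: float = _LOG_FLOOR,
) -> float:
    """Evaluate the entropy-like replicate-separation metric for weights w."""
    if paths.n_replicates < 2:
        raise ValidationError("metric needs at least two replicates")
    if mode not in ("projection", "per_pc"):
        raise ValidationError(f"unknown metric mode {mode!r}")
    diffs = _pc_diffs(paths, basis, w.first_pc, w.weights.size)
    if mode == "projection":
        d2 = (diffs @ w.weights) ** 2
    else:
        d2 = (diffs**2) @ (w.weights**2)
    n_rep = paths.n_replicates
    return float(2.0 / (n_rep * (n_rep - 1)) * np.log(np.maximum(d2, eps)).sum())


@dataclass(frozen=True)
class OptimizeResult:
    weights: WeightVector
    metric: float
    n_evaluations: int
    seed: int
    mode: str


def optimize_pc2(
    paths: PathEnsembleSet,
    basis: PCBasis,
    bounds: float = 1.0,
    seed: int = 2024,
    mode: str = "projection",
    maxiter: int = 300,
    tol: float = 1e-7,
    popsize: int = 15,
    first_pc: int = 2,
) -> OptimizeResult:
    """Find the PC-2..16 combination that best separates the replicates.

    Global stochastic maximisation of :func:`path_separation_metric` by
    differential evolution with per-weight bounds [-bounds, bounds].  If
    the basis holds fewer than 16 components, all components beyond the
    first are used.  The returned weights are unit-norm with the largest
    weight positive; by construction no weight is ever placed on PC 1.
    """
    n_pcs = min(N_COMBINED_PCS, basis.n_components - (first_pc - 1))
    if n_pcs < 1:
        raise ValidationError("basis has no components beyond PC 1")
    diffs = _pc_diffs(paths, basis, first_pc, n_pcs)
    n_rep = paths.n_replicates
    if n_rep < 2:
        raise ValidationError("need at least two replicates")
    prefactor = 2.0 / (n_rep * (n_rep - 1))

    def negative_metric(w: np.ndarray) -> float:
        norm = np.linalg.norm(w)
        if norm < 1e-8:
            return np.inf  # degenerate direction, reject
        w = w / norm
        if mode == "projection":
            d2 = (diffs @ w) ** 2
        else:
            d2 = (diffs**2) @ (w**2)
        val = prefactor * np.log(np.maximum(d2, _LOG_FLOOR)).sum()
        return -val if np.isfinite(val) else np.inf

    result = differential_evolution(
        negative_metric,
        bounds=[(-bounds, bounds)] * n_pcs,
        seed=seed,
        maxiter=maxiter,
        tol=tol,
        popsize=popsize,
        polish=True,
    )
    w = result.x / np.linalg.norm(result.x)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w  # metric is even in w; canonicalise the sign
    weights = WeightVector(w, first_pc=first_pc)
    metric = path_separation_metric(paths, weights, basis, mode=mode)
    return OptimizeResult(weights, metric, int(result.nfev), seed, mode)
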