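"""PCA of trajectory/path frames and 2D-CV projection.

Frames are flat coordinate vectors.  With ``align=True`` they are treated
as 3N Cartesian coordinates and superposed onto the ensemble mean shape by
least-squares rigid fitting (Kabsch) before the covariance is formed —
the conventional way of removing rigid-body motion in trajectory PCA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colvar import CVSeries
from .errors import ValidationError

__all__ = ["PCBasis", "WeightVector", "pca_fit", "project_2d"]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class PCBasis:
    mean: np.ndarray  # (dim,)
    components: np.ndarray  # (n_components, dim), rows orthonormal
    fractions: np.ndarray  # explained-variance fractions, nonincreasing

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        frac = np.asarray(self.fractions, dtype=float)
        if comp.ndim != 2 or frac.shape != (comp.shape[0],):
            raise ValidationError("components/fractions shape mismatch")
        gram = comp @ comp.T
        if not np.allclose(gram, np.eye(comp.shape[0]), atol=1e-8):
            raise ValidationError("components are not orthonormal")
        if np.any(np.diff(frac) > 1e-12):
            raise ValidationError("variance fractions must be nonincreasing")
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "fractions", frac)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, frames: np.ndarray) -> np.ndarray:
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        if frames.shape[1] != self.mean.size:
            raise ValidationError("frame dimensionality does not match the basis")
        return (frames - self.mean) @ self.components.T

    def to_json(self, path: str | Path, **extra) -> Path:
        path = Path(path)
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "fractions": self.fractions.tolist(),
            **extra,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCBasis":
        raw = json.loads(Path(path).read_text())
        return cls(np.array(raw["mean"]), np.array(raw["components"]),
                   np.array(raw["fractions"]))


@dataclass(frozen=True)
class WeightVector:
    """Weights over PCs 2..16 (or fewer if the basis is smaller)."""

    weights: np.ndarray
    first_pc: int = 2  # 1-based index of the first PC carrying weight
    normalized: bool = True

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.normalized:
            norm = np.linalg.norm(w)
            if not np.isclose(norm, 1.0, atol=1e-8):
                raise ValidationError("normalized WeightVector must have unit norm")
        object.__setattr__(self, "weights", w)

    def direction(self, basis: PCBasis) -> np.ndarray:
        """The combined direction v = sum_k w_k PC_k in frame space."""
        lo = self.first_pc - 1
        hi = lo + self.weights.size
        if hi > basis.n_components:
            raise ValidationError("weight vector spans more PCs than the basis has")
        return self.weights @ basis.components[lo:hi]


def _kabsch_align(frames: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Superpose each frame (3N coords) onto the iteratively refined mean."""
    if frames.shape[1] % 3 != 0:
        raise ValidationError("align=True requires 3N coordinate vectors")
    coords = frames.reshape(len(frames), -1, 3).copy()
    coords -= coords.mean(axis=1, keepdims=True)
    ref = coords[0].copy()
    for _ in range(n_iter):
        for i, frame in enumerate(coords):
            h = frame.T @ ref
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, d]) @ vt
            coords[i] = frame @ rot
        ref = coords.mean(axis=0)
    return coords.reshape(len(frames), -1)


def pca_fit(frames: np.ndarray, align: bool = False) -> PCBasis:
    """Eigendecomposition of the covariance of (optionally aligned) frames.

    Rank-deficient input yields only the components with nonzero variance,
    with a warning.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 2:
        raise ValidationError("need at least two frames for PCA")
    if align:
        frames = _kabsch_align(frames)
    mean = frames.mean(axis=0)
    centred = frames - mean
    # SVD of the centred data matrix: eigenvalues of cov = s^2 / (n - 1)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValidationError("frames have zero variance")
    keep = var > _RANK_TOL * total
    if keep.sum() < min(frames.shape[0] - 1, frames.shape[1]):
        warnings.warn(
            f"rank-deficient input: returning {int(keep.sum())} components",
            stacklevel=2,
        )
    return PCBasis(mean, vt[keep], var[keep] / total)


def project_2d(
    frames: np.ndarray,
    basis: PCBasis,
    pc2: WeightVector,
    times: np.ndarray | None = None,
) -> CVSeries:
    """Project frames onto (PC 1, optimised second direction)."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[1] != basis.mean.size:
        raise ValidationError("frame dimensionality does not match the basis")
    centred = frames - basis.mean
    p1 = centred @ basis.components[0]
    p2 = centred @ pc2.direction(basis)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return CVSeries(("pc1", "pc2"), times, np.column_stack([p1, p2]))
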