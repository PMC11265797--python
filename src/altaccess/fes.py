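"""Weighted-histogram (WHAM) estimation of 1D/2D free-energy surfaces.

Umbrella windows with harmonic biases — possibly pooled across path
replicates and across force-constant tiers — are combined into a binned
potential of mean force by solving the self-consistent WHAM equations

    P(b) = N(b) / sum_j N_j exp(beta (f_j - b_j(b)))
    f_j  = -kT ln sum_b P(b) exp(-beta b_j(b)),

where N(b) are pooled counts in bin b, N_j the sample count of window j
and b_j the bias evaluated at the bin centre.  The solver first minimises
the equivalent convex negative log-likelihood with L-BFGS and then
polishes with direct iteration until max |delta beta f| < tol.  Bins with
zero pooled counts are left undefined (+inf free energy); surfaces are
reported zeroed at their defined minimum and are meaningful only up to an
additive constant, which is why alignment helpers are part of the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import units
from .errors import ConvergenceError, ValidationError
from .sampling import BiasSpec, UmbrellaWindow

__all__ = [
    "PMFGrid",
    "ConvergenceBand",
    "wham",
    "project_pmf",
    "align_pmf",
    "convergence_band",
    "basin_barrier_report",
    "pmf_to_csv",
    "pmf_from_csv",
]


@dataclass(frozen=True)
class PMFGrid:
    """Binned free-energy surface in kcal/mol.

    ``values`` is +inf wherever ``defined`` is False.
    """

    edges: tuple[np.ndarray, ...]
    values: np.ndarray
    defined: np.ndarray
    temperature: float = units.DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        values = np.asarray(self.values, dtype=float)
        defined = np.asarray(self.defined, dtype=bool)
        if values.ndim != len(edges) or values.ndim not in (1, 2):
            raise ValidationError("PMFGrid must be 1D or 2D with matching edges")
        for dim, e in enumerate(edges):
            if e.size != values.shape[dim] + 1:
                raise ValidationError("edges must have one more entry than bins")
            if not np.all(np.diff(e) > 0):
                raise ValidationError("bin edges must be strictly increasing")
        if defined.shape != values.shape:
            raise ValidationError("defined mask shape mismatch")
        if not defined.any():
            raise ValidationError("surface has no defined bins")
        values = np.where(defined, values, np.inf)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "defined", defined)

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def centres(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def zeroed(self) -> "PMFGrid":
        shift = self.values[self.defined].min()
        return replace(self, values=np.where(self.defined, self.values - shift, np.inf))

    def shifted(self, constant: float) -> "PMFGrid":
        return replace(
            self, values=np.where(self.defined, self.values + constant, np.inf)
        )


@dataclass(frozen=True)
class ConvergenceBand:
    """Envelope of aligned PMF curves across sampling fractions."""

    centres: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    curves: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        both = np.isfinite(self.lower) & np.isfinite(self.upper)
        if np.any(self.lower[both] > self.upper[both] + 1e-12):
            raise ValidationError("band lower envelope exceeds upper envelope")

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower


def _grid_edges(windows: Sequence[UmbrellaWindow], bins) -> tuple[np.ndarray, ...]:
    ndim = windows[0].samples.n_cvs
    if isinstance(bins, int):
        bins = (bins,) * ndim
    edges = []
    all_vals = np.concatenate([w.samples.values for w in windows], axis=0)
    for d in range(ndim):
        b = bins[d]
        if np.ndim(b) == 0:
            lo, hi = all_vals[:, d].min(), all_vals[:, d].max()
            pad = 1e-9 * max(1.0, abs(hi - lo))
            edges.append(np.linspace(lo - pad, hi + pad, int(b) + 1))
        else:
            edges.append(np.asarray(b, dtype=float))
    return tuple(edges)


def _check_overlap(counts_per_window: np.ndarray) -> None:
    """Warn when windows split into histogram-disconnected components."""
    n_win = counts_per_window.shape[0]
    occupied = counts_per_window > 0
    adj = (occupied @ occupied.T) > 0
    labels = -np.ones(n_win, dtype=int)
    n_comp = 0
    for start in range(n_win):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = n_comp
        while stack:
            node = stack.pop()
            for other in np.flatnonzero(adj[node]):
                if labels[other] < 0:
                    labels[other] = n_comp
                    stack.append(other)
        n_comp += 1
    if n_comp > 1:
        groups = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        warnings.warn(
            f"window histograms form {n_comp} disconnected components: {groups}; "
            "relative free energies between components are meaningless",
            stacklevel=3,
        )


def wham(
    windows: Sequence[UmbrellaWindow],
    bins: int | Sequence = 72,
    temperature: float = units.DEFAULT_TEMPERATURE,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFGrid:
    """Solve WHAM for pooled umbrella windows.

    ``bins`` is an int (per dimension), a sequence of per-dimension counts,
    or a sequence of explicit edge arrays.  Heterogeneous force constants
    and pooled replicate/tier labels need no special handling: each window
    enters with its own bias.  The default grid is 72 bins in 1D; pass
    ``(48, 48)`` for the canonical 2D grid.
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("need at least one window")
    ndim = windows[0].samples.n_cvs
    if any(w.samples.n_cvs != ndim for w in windows):
        raise ValidationError("windows have inconsistent dimensionality")
    if isinstance(bins, int):
        bins = (bins,) * ndim
    edges = _grid_edges(windows, bins)
    centres = tuple(0.5 * (e[1:] + e[:-1]) for e in edges)
    shape = tuple(c.size for c in centres)
    n_bins = int(np.prod(shape))
    n_win = len(windows)

    counts_per_window = np.zeros((n_win, n_bins))
    for j, w in enumerate(windows):
        h, _ = np.histogramdd(w.samples.values, bins=edges)
        counts_per_window[j] = h.ravel()
    _check_overlap(counts_per_window)
    pooled = counts_per_window.sum(axis=0)
    n_samples = counts_per_window.sum(axis=1)

    if ndim == 1:
        grid_points = centres[0][:, None]
    else:
        xx, yy = np.meshgrid(centres[0], centres[1], indexing="ij")
        grid_points = np.column_stack([xx.ravel(), yy.ravel()])
    b = units.beta(temperature)
    # log exp(-beta bias_j(bin)); underflows to -inf harmlessly far from centres
    log_bias_weight = np.stack(
        [-b * w.bias.energy(grid_points) for w in windows]
    )  # (n_win, n_bins)

    occupied = pooled > 0
    log_pooled = np.where(occupied, np.log(np.maximum(pooled, 1)), -np.inf)
    log_n = np.log(n_samples)

    def neg_log_likelihood(g: np.ndarray):
        # A(g) = sum_b N(b) ln D_b(g) - sum_j N_j g_j  (convex up to gauge)
        log_denominator = logsumexp(
            log_n[:, None] + g[:, None] + log_bias_weight, axis=0
        )
        value = (pooled[occupied] * log_denominator[occupied]).sum() - (
            n_samples * g
        ).sum()
        # gradient: sum_b N(b) w_jb - N_j with w_jb the window responsibility
        resp = np.exp(log_n[:, None] + g[:, None] + log_bias_weight - log_denominator)
        grad = (resp[:, occupied] * pooled[occupied]).sum(axis=1) - n_samples
        return value, grad

    g = np.zeros(n_win)
    result = minimize(
        neg_log_likelihood, g, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    g = result.x - result.x[0]

    converged = False
    for _ in range(max_iter):
        log_denominator = logsumexp(
            log_n[:, None] + g[:, None] + log_bias_weight, axis=0
        )
        log_p = np.where(occupied, log_pooled - log_denominator, -np.inf)
        log_p -= logsumexp(log_p[occupied])
        g_new = -logsumexp(log_p[None, occupied] + log_bias_weight[:, occupied], axis=1)
        g_new -= g_new[0]
        delta = np.abs(g_new - g).max()
        g = g_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3e})"
        )

    log_denominator = logsumexp(log_n[:, None] + g[:, None] + log_bias_weight, axis=0)
    log_p = np.where(occupied, log_pooled - log_denominator, -np.inf)
    kt = units.kt(temperature)
    with np.errstate(divide="ignore"):
        free_energy = np.where(occupied, -kt * log_p, np.inf).reshape(shape)
    grid = PMFGrid(edges, free_energy, occupied.reshape(shape), temperature)
    return grid.zeroed()


def project_pmf(pmf: PMFGrid, axis: int = 1) -> PMFGrid:
    """Boltzmann-reweighted projection of a 2D surface onto one axis.

    F1(x) = -kT ln sum_y exp(-beta F2(x, y)) dy over defined bins; columns
    with no defined bins stay undefined.  Undefined bins carry zero
    probability, consistent with their +inf free energy.
    """
    if pmf.ndim != 2:
        raise ValidationError("project_pmf needs a 2D surface")
    if axis not in (1, 2):
        raise ValidationError("axis must be 1 or 2")
    keep = axis - 1
    other = 1 - keep
    kt = units.kt(pmf.temperature)
    widths = np.diff(pmf.edges[other])
    values = np.moveaxis(pmf.values, keep, 0)  # (kept_bins, other_bins)
    defined = np.moveaxis(pmf.defined, keep, 0)
    out = np.full(values.shape[0], np.inf)
    mask = defined.any(axis=1)
    for i in np.flatnonzero(mask):
        row_def = defined[i]
        out[i] = -kt * logsumexp(
            -values[i, row_def] / kt, b=widths[row_def]
        )
    if not mask.any():
        raise ValidationError("projection of a fully undefined surface")
    grid = PMFGrid((pmf.edges[keep],), out, mask, pmf.temperature)
    return grid.zeroed()


def align_pmf(
    pmf: PMFGrid,
    reference: PMFGrid | None = None,
    region: tuple[float, float] | None = None,
) -> PMFGrid:
    """Fix the additive constant of a 1D profile.

    Curve mode (``reference``): add the constant minimising the squared
    deviation from the reference over co-defined bins — the mean
    difference over the overlap.  State mode (``region``): shift so the
    mean over the stated CV interval is zero.
    """
    if pmf.ndim != 1:
        raise ValidationError("align_pmf operates on 1D profiles")
    if (reference is None) == (region is None):
        raise ValidationError("pass exactly one of reference or region")
    centres = pmf.centres[0]
    if reference is not None:
        if reference.ndim != 1:
            raise ValidationError("reference must be 1D")
        if reference.values.shape != pmf.values.shape or not np.allclose(
            reference.edges[0], pmf.edges[0]
        ):
            raise ValidationError("reference grid does not match")
        both = pmf.defined & reference.defined
        if not both.any():
            raise ValidationError("no co-defined bins to align on")
        shift = float((reference.values[both] - pmf.values[both]).mean())
    else:
        lo, hi = region
        mask = pmf.defined & (centres >= lo) & (centres <= hi)
        if not mask.any():
            raise ValidationError(f"no defined bins in region [{lo}, {hi}]")
        shift = -float(pmf.values[mask].mean())
    return pmf.shifted(shift)


def _truncate_window(window: UmbrellaWindow, fraction: tuple[float, float]) -> UmbrellaWindow:
    lo_frac, hi_frac = fraction
    n = window.samples.n_frames
    lo, hi = int(np.floor(lo_frac * n)), int(np.ceil(hi_frac * n))
    if hi - lo < 1:
        raise ValidationError("sampling fraction selects no frames")
    return replace(window, samples=window.samples.slice_frames(lo, hi))


def convergence_band(
    windows: Sequence[UmbrellaWindow],
    fractions: Sequence[tuple[float, float]] = ((0.0, 0.4), (0.6, 1.0), (0.0, 1.0)),
    bins: int | Sequence = 72,
    temperature: float = units.DEFAULT_TEMPERATURE,
    project_axis: int = 1,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> ConvergenceBand:
    """Convergence error band from time-truncated re-estimates.

    The full pipeline (WHAM, then projection when the windows are 2D) is
    repeated with each per-window time fraction — by default the first
    40%, the last 40% and all of the sampling — each re-aligned to the
    100% profile, and the band is the per-bin min/max envelope.  The 100%
    curve lies inside the band by construction.
    """
    windows = list(windows)
    ndim = windows[0].samples.n_cvs
    if isinstance(bins, int):
        bins = (bins,) * ndim
    edges = _grid_edges(windows, bins)  # shared grid across fractions

    def profile(fraction):
        trunc = [_truncate_window(w, fraction) for w in windows]
        grid = wham(trunc, bins=edges, temperature=temperature,
                    tolerance=tolerance, max_iter=max_iter)
        return project_pmf(grid, axis=project_axis) if ndim == 2 else grid

    full_key = (0.0, 1.0)
    fractions = list(fractions)
    if full_key not in fractions:
        fractions.append(full_key)
    full = profile(full_key)
    curves: dict[str, np.ndarray] = {}
    stack = []
    for frac in fractions:
        prof = full if frac == full_key else align_pmf(profile(frac), reference=full)
        vals = np.where(prof.defined, prof.values, np.nan)
        curves[f"{frac[0]:.2f}-{frac[1]:.2f}"] = vals
        stack.append(vals)
    arr = np.stack(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        lower = np.nanmin(arr, axis=0)
        upper = np.nanmax(arr, axis=0)
    return ConvergenceBand(full.centres[0], lower, upper, curves)


def _prune_minima(values: np.ndarray, minima: np.ndarray, min_prominence: float) -> np.ndarray:
    """Iteratively drop the least prominent minimum until all survivors
    rise at least ``min_prominence`` to the lower of their flanking saddles."""
    minima = list(minima)
    while len(minima) > 1:
        proms = []
        for pos, idx in enumerate(minima):
            saddles = []
            if pos > 0:
                saddles.append(values[minima[pos - 1] : idx + 1].max())
            if pos < len(minima) - 1:
                saddles.append(values[idx : minima[pos + 1] + 1].max())
            proms.append(min(saddles) - values[idx])
        weakest = int(np.argmin(proms))
        if proms[weakest] >= min_prominence:
            break
        del minima[weakest]
    return np.asarray(minima, dtype=int)


def basin_barrier_report(
    pmf: PMFGrid,
    smoothing: int | None = None,
    min_prominence: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Locate basins and inter-basin barriers on a 1D profile.

    Returns two tables: ``minima`` (position, free energy relative to the
    global minimum) and ``barriers`` (for each adjacent basin pair, the
    saddle position/height and the barrier seen from either basin).
    ``smoothing`` is an optional moving-average window in bins;
    ``min_prominence`` (kcal/mol) prunes shallow minima whose relief over
    the lower of the saddles flanking them falls below the threshold —
    the standard guard against reading statistical jitter as basins.  A
    monotone profile has no interior minima and yields empty tables with a
    note.
    """
    if pmf.ndim != 1:
        raise ValidationError("basin_barrier_report operates on 1D profiles")
    centres = pmf.centres[0][pmf.defined]
    values = pmf.values[pmf.defined]
    if smoothing is not None and smoothing > 1:
        kernel = np.ones(int(smoothing)) / int(smoothing)
        pad = int(smoothing) // 2
        padded = np.pad(values, pad, mode="edge")
        values = np.convolve(padded, kernel, mode="same")[pad : pad + centres.size]
    interior = np.flatnonzero(
        (values[1:-1] < values[:-2]) & (values[1:-1] <= values[2:])
    ) + 1
    interior = _prune_minima(values, interior, min_prominence)
    note = "" if interior.size else "profile has no interior minima"
    minima = pd.DataFrame(
        {
            "position": centres[interior],
            "delta_g": values[interior] - (values[interior].min() if interior.size else 0.0),
        }
    )
    rows = []
    for a, b in zip(interior[:-1], interior[1:]):
        saddle_rel = np.argmax(values[a : b + 1])
        saddle = a + saddle_rel
        rows.append(
            {
                "left_position": centres[a],
                "right_position": centres[b],
                "saddle_position": centres[saddle],
                "saddle_value": values[saddle] - values[interior].min(),
                "barrier_from_left": values[saddle] - values[a],
                "barrier_from_right": values[saddle] - values[b],
                "delta_g_right_minus_left": values[b] - values[a],
            }
        )
    barriers = pd.DataFrame(
        rows,
        columns=[
            "left_position", "right_position", "saddle_position", "saddle_value",
            "barrier_from_left", "barrier_from_right", "delta_g_right_minus_left",
        ],
    )
    return {"minima": minima, "barriers": barriers, "note": note}


def pmf_to_csv(pmf: PMFGrid, path) -> None:
    """Write a PMF as a CSV of bin centres, value and defined flag."""
    centres = pmf.centres
    if pmf.ndim == 1:
        df = pd.DataFrame(
            {"cv1": centres[0], "free_energy": np.where(pmf.defined, pmf.values, np.nan),
             "defined": pmf.defined}
        )
    else:
        xx, yy = np.meshgrid(centres[0], centres[1], indexing="ij")
        df = pd.DataFrame(
            {
                "cv1": xx.ravel(),
                "cv2": yy.ravel(),
                "free_energy": np.where(pmf.defined, pmf.values, np.nan).ravel(),
                "defined": pmf.defined.ravel(),
            }
        )
    df.to_csv(path, index=False)


def _edges_from_centres(centres: np.ndarray) -> np.ndarray:
    mids = 0.5 * (centres[1:] + centres[:-1])
    first = centres[0] - (mids[0] - centres[0])
    last = centres[-1] + (centres[-1] - mids[-1])
    return np.concatenate([[first], mids, [last]])


def pmf_from_csv(path, temperature: float = units.DEFAULT_TEMPERATURE) -> PMFGrid:
    """Read back a PMF written by :func:`pmf_to_csv` (uniform grids)."""
    df = pd.read_csv(path)
    if "cv2" in df.columns:
        x = np.unique(df["cv1"].values)
        y = np.unique(df["cv2"].values)
        values = df["free_energy"].values.reshape(x.size, y.size)
        defined = df["defined"].values.reshape(x.size, y.size).astype(bool)
        edges = (_edges_from_centres(x), _edges_from_centres(y))
    else:
        x = df["cv1"].values
        values = df["free_energy"].values
        defined = df["defined"].values.astype(bool)
        edges = (_edges_from_centres(x),)
    values = np.where(defined, values, np.inf)
    return PMFGrid(edges, values, defined, temperature)
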