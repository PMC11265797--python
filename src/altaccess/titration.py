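"""pKa analysis of per-pH protonation traces.

The titration curve convention used throughout: the *deprotonated*
fraction rises with pH,

    f_deprot(pH) = 1 / (1 + 10^(n (pKa - pH))),

with Hill coefficient n fixed to 1 by default (single-site residues).
pKa shifts convert to protonation free energies via RT ln(10) per log
unit; the sign convention is centralised in :func:`pka_shift_to_ddg` and
:mod:`altaccess.thermo` (protonation edges) so it is defined exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import units
from .errors import UnidentifiableError, ValidationError

__all__ = [
    "ProtonationSeries",
    "PkaEstimate",
    "deprotonated_fractions",
    "fit_titration",
    "chunked_pka",
    "replicate_stats",
    "pka_shift_to_ddg",
]


@dataclass(frozen=True)
class ProtonationSeries:
    """Binary protonation traces (1 = protonated) for one residue across
    a ladder of pH replicas."""

    residue: str
    ph_values: tuple[float, ...]
    traces: np.ndarray  # (n_ph, n_frames) of 0/1
    frame_period_ns: float = 1.0

    def __post_init__(self) -> None:
        ph = tuple(float(p) for p in self.ph_values)
        traces = np.asarray(self.traces)
        if traces.ndim != 2 or traces.shape[0] != len(ph):
            raise ValidationError("traces must have one row per pH value")
        if traces.shape[1] == 0:
            raise ValidationError("traces are empty")
        if len(set(ph)) != len(ph):
            raise ValidationError("pH values must be distinct")
        if not np.isin(traces, (0, 1)).all():
            raise ValidationError("traces must be binary (1 = protonated)")
        if self.frame_period_ns <= 0:
            raise ValidationError("frame_period_ns must be positive")
        object.__setattr__(self, "ph_values", ph)
        object.__setattr__(self, "traces", traces.astype(np.int8))

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class PkaEstimate:
    pka: float
    hill: float
    residual: float
    source: str = "full"  # or "chunk"
    chunk_start_ns: float | None = None
    chunk_length_ns: float | None = None

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValidationError("Hill coefficient must be positive")


def deprotonated_fractions(
    series: ProtonationSeries,
    frame_range: tuple[int, int] | None = None,
) -> pd.Series:
    """Per-pH mean deprotonated fraction over a frame range."""
    lo, hi = (0, series.n_frames) if frame_range is None else frame_range
    chunk = series.traces[:, lo:hi]
    if chunk.shape[1] == 0:
        raise ValidationError("empty frame range")
    frac = 1.0 - chunk.mean(axis=1)
    return pd.Series(frac, index=list(series.ph_values), name="f_deprot").sort_index()


def _hill_curve(ph: np.ndarray, pka: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (hill * (pka - ph)))


def fit_titration(fractions: pd.Series, fit_hill: bool = False) -> PkaEstimate:
    """Least-squares fit of the Hill titration curve to per-pH fractions.

    The pKa is constrained to [min(pH) - 2, max(pH) + 2]; traces that are
    entirely protonated or entirely deprotonated at every pH carry no
    information about the midpoint and raise :class:`UnidentifiableError`.
    """
    ph = np.asarray(fractions.index, dtype=float)
    f = np.asarray(fractions.values, dtype=float)
    if ph.size < 2:
        raise ValidationError("need at least two pH points")
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("fractions must lie in [0, 1]")
    if np.all(f <= 0.0) or np.all(f >= 1.0):
        raise UnidentifiableError(
            "titration curve is saturated at every pH; pKa is unidentifiable"
        )
    lo, hi = ph.min() - 2.0, ph.max() + 2.0
    # midpoint-crossing initial guess
    order = np.argsort(ph)
    pka0 = float(np.clip(np.interp(0.5, f[order], ph[order]), lo, hi))
    if fit_hill:
        x0, lb, ub = [pka0, 1.0], [lo, 0.05], [hi, 10.0]
        fun = lambda p: _hill_curve(ph, p[0], p[1]) - f
    else:
        x0, lb, ub = [pka0], [lo], [hi]
        fun = lambda p: _hill_curve(ph, p[0], 1.0) - f
    res = least_squares(fun, x0, bounds=(lb, ub))
    pka = float(res.x[0])
    hill = float(res.x[1]) if fit_hill else 1.0
    return PkaEstimate(pka=pka, hill=hill, residual=float(np.sum(res.fun**2)))


def chunked_pka(
    series: ProtonationSeries,
    chunk_ns: float,
    fit_hill: bool = False,
    histogram_bins: int | Sequence[float] = 30,
) -> tuple[list[PkaEstimate], tuple[np.ndarray, np.ndarray], int]:
    """pKa estimates from consecutive non-overlapping time chunks.

    Returns the per-chunk estimates, a histogram (counts, bin edges) over
    the identifiable estimates, and the number of chunks skipped because
    they were saturated at every pH (excluded rather than clamped, which
    would fabricate mass at the pH-range edges).
    """
    frames_per_chunk = int(round(chunk_ns / series.frame_period_ns))
    if frames_per_chunk < 1:
        raise ValidationError("chunk shorter than one frame")
    if frames_per_chunk > series.n_frames:
        raise ValidationError("chunk longer than the trace")
    estimates: list[PkaEstimate] = []
    skipped = 0
    n_chunks = series.n_frames // frames_per_chunk
    for i in range(n_chunks):
        lo = i * frames_per_chunk
        frac = deprotonated_fractions(series, (lo, lo + frames_per_chunk))
        try:
            est = fit_titration(frac, fit_hill=fit_hill)
        except UnidentifiableError:
            skipped += 1
            continue
        estimates.append(
            PkaEstimate(
                est.pka, est.hill, est.residual, source="chunk",
                chunk_start_ns=lo * series.frame_period_ns,
                chunk_length_ns=frames_per_chunk * series.frame_period_ns,
            )
        )
    values = np.array([e.pka for e in estimates])
    counts, edges = np.histogram(values, bins=histogram_bins) if values.size else (
        np.array([], dtype=int), np.array([]))
    return estimates, (counts, edges), skipped


def replicate_stats(estimates: Sequence[PkaEstimate | float]) -> tuple[float, float | None]:
    """Mean and sample standard deviation (n-1 denominator) across replicates.

    With fewer than two replicates the SD is undefined and returned as None.
    """
    values = np.array(
        [e.pka if isinstance(e, PkaEstimate) else float(e) for e in estimates]
    )
    if values.size == 0:
        raise ValidationError("no replicate estimates")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return mean, sd


def pka_shift_to_ddg(
    delta_pka: float, temperature: float = units.DEFAULT_TEMPERATURE
) -> float:
    """Free-energy change of protonation for a pKa shift.

    A raised pKa (positive delta) means protonation became more favourable:
    ddG = -RT ln(10) * delta_pKa, in kcal/mol.
    """
    return -units.rt_ln10(temperature) * delta_pka
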