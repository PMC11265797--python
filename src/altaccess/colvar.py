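"""Collective-variable time series and their on-disk COLVAR format.

The COLVAR dialect accepted here is the whitespace-table family written by
biasing plugins: a header line ``#! FIELDS time <label> ...`` followed by
one row of numbers per frame.  Additional lines starting with ``#`` are
treated as comments and skipped.  The reader is schema-driven by the header
rather than expecting fixed column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["CVSeries", "read_colvar", "write_colvar"]


@dataclass(frozen=True)
class CVSeries:
    """Time-stamped values of one or more collective variables.

    Parameters
    ----------
    labels:
        One name per CV column (the time column is not a label).
    times:
        Strictly increasing sample times in ps.
    values:
        Array of shape ``(n_frames, n_cvs)``; nm for gate CVs, arbitrary
        units for principal-component projections.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[0] == 1 and times.size > 1:
            values = values.T
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if times.size == 0:
            raise ValidationError("no samples")
        if values.shape[0] != times.size:
            raise ValidationError(
                f"row count {values.shape[0]} does not match time count {times.size}"
            )
        if values.shape[1] != len(self.labels):
            raise ValidationError(
                f"column count {values.shape[1]} does not match label count {len(self.labels)}"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        for lab in self.labels:
            if not lab or any(c.isspace() for c in lab):
                raise ValidationError(f"label {lab!r} is empty or contains whitespace")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_cvs(self) -> int:
        return len(self.labels)

    def column(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no CV named {label!r}; have {self.labels}") from None
        return self.values[:, idx]

    def slice_frames(self, start: int, stop: int | None = None) -> "CVSeries":
        sl = slice(start, stop)
        times = self.times[sl]
        if times.size == 0:
            raise ValidationError("frame slice selects no samples")
        return CVSeries(self.labels, times, self.values[sl])


def read_colvar(path: str | Path) -> CVSeries:
    """Read a COLVAR-style whitespace table.

    The first field named in the ``#! FIELDS`` header must be time; the
    remaining fields become the CV labels.
    """
    path = Path(path)
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#!") and "FIELDS" in line:
                    tokens = line.split()
                    fields = tokens[tokens.index("FIELDS") + 1 :]
                    if not fields:
                        raise FormatError(f"{path}: FIELDS header names no columns")
                    labels = fields
                continue
            if labels is None:
                raise FormatError(f"{path}: data before '#! FIELDS' header")
            tokens = line.split()
            if len(tokens) != len(labels):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(labels)} columns, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric token") from exc
    if labels is None:
        raise FormatError(f"{path}: missing '#! FIELDS' header")
    if not rows:
        raise ValidationError(f"{path}: no samples")
    data = np.array(rows, dtype=float)
    return CVSeries(tuple(labels[1:]), data[:, 0], data[:, 1:])


def write_colvar(series: CVSeries, path: str | Path) -> Path:
    """Write a CVSeries as a COLVAR table (inverse of :func:`read_colvar`)."""
    path = Path(path)
    header = "#! FIELDS time " + " ".join(series.labels)
    table = np.column_stack([series.times, series.values])
    with path.open("w") as fh:
        fh.write(header + "\n")
        for row in table:
            fh.write(" ".join(f"{x: .12e}" for x in row) + "\n")
    return path
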