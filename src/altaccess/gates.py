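"""Gate collective variables and contact statistics on coordinate frames.

The extracellular and intracellular gates of an alternating-access MFS
transporter are tracked as centre-of-mass distances between the helical
tips (extracellular ends) and bases (intracellular ends) of the N- and
C-terminal six-helix bundles, evaluated over the Calpha atoms of fixed
residue intervals.  The built-in definitions carry the residue numbering
of rat PepT2 (SLC15A2) with its extracellular domain truncated; no
renumbering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .colvar import CVSeries
from .errors import SelectionError, ValidationError
from .structure import StructureFrame

__all__ = [
    "ResidueGroup",
    "GateCVDefinition",
    "ContactSpec",
    "builtin_gate_cvs",
    "center_of_mass",
    "gate_cv",
    "gate_cv_series",
    "contact_fraction",
]


@dataclass(frozen=True)
class ResidueGroup:
    """A set of residues given as inclusive id intervals plus an atom-name
    filter (Calpha by default; None selects all atoms of the residues)."""

    label: str
    ranges: tuple[tuple[int, int], ...]
    atom_name: str | None = "CA"

    def __post_init__(self) -> None:
        ranges = tuple((int(lo), int(hi)) for lo, hi in self.ranges)
        if not ranges:
            raise ValidationError(f"group {self.label!r} has no residue ranges")
        if any(lo > hi for lo, hi in ranges):
            raise ValidationError(f"group {self.label!r} has an inverted interval")
        object.__setattr__(self, "ranges", ranges)

    def residue_ids(self) -> np.ndarray:
        ids: list[int] = []
        for lo, hi in self.ranges:
            ids.extend(range(lo, hi + 1))
        return np.unique(ids)

    def atom_indices(self, frame: StructureFrame) -> np.ndarray:
        mask = np.isin(frame.resids, self.residue_ids())
        if self.atom_name is not None:
            mask &= frame.names == self.atom_name
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            missing = ", ".join(f"{lo}-{hi}" for lo, hi in self.ranges)
            raise SelectionError(
                f"group {self.label!r} (residues {missing}, atom "
                f"{self.atom_name or 'any'}) matched no atoms"
            )
        return idx


@dataclass(frozen=True)
class GateCVDefinition:
    """Inter-bundle COM distance between two residue groups."""

    name: str
    group_a: ResidueGroup
    group_b: ResidueGroup
    check_disjoint: bool = True

    def __post_init__(self) -> None:
        if self.check_disjoint:
            shared = np.intersect1d(self.group_a.residue_ids(), self.group_b.residue_ids())
            if shared.size:
                raise ValidationError(
                    f"CV {self.name!r}: groups share residues {shared.tolist()}"
                )


@dataclass(frozen=True)
class ContactSpec:
    """Minimum-distance contact between two selections, cutoff in nm."""

    selection_a: ResidueGroup
    selection_b: ResidueGroup
    cutoff: float = 0.4

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("contact cutoff must be positive")


# Residue intervals defining the bundle tips and bases (12 residues per
# helix end, six helices per bundle => 72 residues per group).
_TIP_N = ((63, 74), (79, 90), (120, 131), (143, 154), (194, 205), (217, 228))
_TIP_C = ((320, 331), (341, 352), (392, 403), (609, 620), (655, 666), (671, 682))
_BASE_N = ((46, 57), (93, 104), (110, 121), (161, 172), (177, 188), (227, 238))
_BASE_C = ((290, 301), (359, 370), (376, 387), (626, 637), (642, 653), (686, 697))


def builtin_gate_cvs() -> tuple[GateCVDefinition, GateCVDefinition]:
    """The built-in tip-CV (extracellular gate) and base-CV (intracellular
    gate) definitions.

    Note the tip and base groups of the same bundle overlap at residues
    227-228; that is permitted since the two groups belong to different
    CVs — disjointness is only enforced within one CV.
    """
    tip = GateCVDefinition(
        "tip",
        ResidueGroup("n_bundle_tips", _TIP_N),
        ResidueGroup("c_bundle_tips", _TIP_C),
    )
    base = GateCVDefinition(
        "base",
        ResidueGroup("n_bundle_bases", _BASE_N),
        ResidueGroup("c_bundle_bases", _BASE_C),
    )
    return tip, base


def center_of_mass(frame: StructureFrame, group: ResidueGroup) -> np.ndarray:
    """Mass-weighted mean position (nm) of the group's atoms in the frame."""
    idx = group.atom_indices(frame)
    m = frame.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValidationError(f"group {group.label!r} has zero total mass")
    return (frame.positions[idx] * m[:, None]).sum(axis=0) / total


def gate_cv(frame: StructureFrame, definition: GateCVDefinition) -> float:
    """Euclidean distance (nm) between the COMs of the two groups."""
    com_a = center_of_mass(frame, definition.group_a)
    com_b = center_of_mass(frame, definition.group_b)
    return float(np.linalg.norm(com_a - com_b))


def gate_cv_series(
    frames: Sequence[StructureFrame],
    definitions: Sequence[GateCVDefinition],
    times: np.ndarray | None = None,
) -> CVSeries:
    """Evaluate one or more gate CVs over a frame sequence."""
    frames = list(frames)
    if not frames:
        raise ValidationError("no frames")
    values = np.array([[gate_cv(f, d) for d in definitions] for f in frames])
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return CVSeries(tuple(d.name for d in definitions), times, values)


def contact_fraction(frames: Sequence[StructureFrame], spec: ContactSpec) -> float:
    """Fraction of frames in which the minimum inter-selection atom
    distance is within the cutoff."""
    frames = list(frames)
    if not frames:
        raise ValidationError("no frames")
    hits = 0
    for frame in frames:
        ia = spec.selection_a.atom_indices(frame)
        ib = spec.selection_b.atom_indices(frame)
        dmin = cdist(frame.positions[ia], frame.positions[ib]).min()
        if dmin <= spec.cutoff:
            hits += 1
    return hits / len(frames)
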