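"""Minimal coordinate frames read from PDB files.

Only what gate-CV evaluation needs is kept: serials, atom names, residue
ids, chains, masses and positions.  Positions are converted from the PDB's
Angstrom convention to nm on ingestion.  Parsing itself is delegated to
MDAnalysis, which also supplies element masses guessed from atom names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["StructureFrame", "read_structure"]


@dataclass(frozen=True)
class StructureFrame:
    """One set of atomic coordinates.

    positions are in nm, masses in amu.
    """

    serials: np.ndarray  # (n,) int
    names: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int
    chains: np.ndarray  # (n,) str
    masses: np.ndarray  # (n,) float, amu
    positions: np.ndarray  # (n, 3) float, nm

    def __post_init__(self) -> None:
        n = len(self.serials)
        for name in ("names", "resids", "chains", "masses"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name} length mismatch")
        if self.positions.shape != (n, 3):
            raise ValidationError("positions must have shape (n_atoms, 3)")
        if len(np.unique(self.serials)) != n:
            raise ValidationError("duplicate atom serials")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "StructureFrame":
        """Return a copy with a rigid-body transform applied (testing aid)."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return StructureFrame(self.serials, self.names, self.resids,
                              self.chains, self.masses, pos)


def read_structure(path: str | Path) -> StructureFrame:
    """Read ATOM/HETATM records from a PDB file into a StructureFrame."""
    import warnings

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        import MDAnalysis as mda

        try:
            universe = mda.Universe(str(path), format="PDB")
        except (ValueError, OSError, IndexError) as exc:
            raise FormatError(f"{path}: not readable as PDB: {exc}") from exc
    atoms = universe.atoms
    if len(atoms) == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    try:
        chains = np.array([str(s) for s in atoms.chainIDs])
    except (mda.exceptions.NoDataError, AttributeError):
        chains = np.array([""] * len(atoms))
    return StructureFrame(
        serials=np.asarray(atoms.ids, dtype=int),
        names=np.array([str(n) for n in atoms.names]),
        resids=np.asarray(atoms.resids, dtype=int),
        chains=chains,
        masses=np.asarray(atoms.masses, dtype=float),
        positions=np.asarray(atoms.positions, dtype=float) / 10.0,  # A -> nm
    )
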