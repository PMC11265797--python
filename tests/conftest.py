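"""Shared fixtures: expensive canonical campaigns are built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def campaign_1d():
    """Canonical 24-window double-well campaign (3 kcal/mol barrier)."""
    from altaccess.protocols import canonical_1d_campaign

    return canonical_1d_campaign(seed=5)


@pytest.fixture(scope="session")
def campaign_2d():
    """Canonical 144-window two-tier campaign on the three-basin surface."""
    from altaccess.protocols import canonical_2d_campaign

    return canonical_2d_campaign(seed=7)


def write_pdb(path, atoms):
    """Write minimal well-formed ATOM records.

    ``atoms``: sequence of (serial, name, resname, chain, resid, x, y, z)
    with coordinates in Angstrom.
    """
    lines = []
    for serial, name, resname, chain, resid, x, y, z in atoms:
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{resname:>3s} {chain:1s}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_frame():
    """A hand-built two-cluster frame for COM/gate tests (no file I/O)."""
    from altaccess.structure import StructureFrame

    # two 4-atom clusters: COMs at origin and at (2.8, 0, 0) nm
    pos = np.array(
        [
            [0.1, 0.0, 0.0], [-0.1, 0.0, 0.0], [0.0, 0.1, 0.0], [0.0, -0.1, 0.0],
            [2.9, 0.0, 0.0], [2.7, 0.0, 0.0], [2.8, 0.1, 0.0], [2.8, -0.1, 0.0],
        ]
    )
    return StructureFrame(
        serials=np.arange(1, 9),
        names=np.array(["CA"] * 8),
        resids=np.array([1, 2, 3, 4, 11, 12, 13, 14]),
        chains=np.array(["A"] * 8),
        masses=np.full(8, 12.011),
        positions=pos,
    )
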