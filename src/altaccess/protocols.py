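"""Canonical synthetic campaign protocols.

These bundle the stock surfaces with the window designs and integrator
settings used throughout the examples, tests and analysis scripts, so the
"stated world" of the synthetic study is defined in exactly one place.

1D protocol: the 3 kcal/mol double well sampled by 24 umbrella windows at
a force constant of 4000 kJ/mol/nm^2 (about 956 kcal/mol/nm^2), 2e4
samples per window.

2D protocol: the three-basin surface sampled by the pooled two-tier
design — 24 centres along the gating coordinate x 2 force-constant tiers
x 3 replicates = 144 windows.  The soft tier (1000/250 kJ/mol/unit^2 in
x/y) covers the basins, the stiff tier (5000/1250) covers the transition
regions; pooling both into one WHAM is the point of the design.  The
y-restraints are softer so that windows cover the basins' orthogonal
width.  The recommended analysis grid is 64 x 48 bins: the x-bin width
must stay comparable to the stiffest window's thermal width, else binned
WHAM picks up discretisation bias.
"""

from __future__ import annotations

import numpy as np

from . import units
from .sampling import LangevinParams, UmbrellaWindow, make_umbrella_campaign
from .surfaces import DoubleWell1D, GaussianBasinMixture, default_double_well, three_basin_surface

__all__ = [
    "canonical_1d_campaign",
    "canonical_2d_campaign",
    "CANONICAL_1D_FORCE_CONSTANT_KJ",
    "CANONICAL_2D_TIERS_KJ",
    "CANONICAL_2D_GRID",
]

CANONICAL_1D_FORCE_CONSTANT_KJ = 4000.0
CANONICAL_2D_TIERS_KJ = ((1000.0, 250.0), (5000.0, 1250.0))
CANONICAL_2D_GRID = (64, 48)

#: 72 bins spanning the window-covered range.  Auto-ranged grids stretch to
#: the rarest excursion and put their outermost bins in barely-sampled
#: territory, which inflates the tails of the recovered profile.  The steep
#: quartic walls also push the outermost windows inward, so coverage ends
#: near 0.22/0.98 nm rather than at the outermost bias centres.
CANONICAL_1D_GRID = (np.linspace(0.22, 0.98, 73),)


def canonical_1d_campaign(
    seed: int = 0,
    n_samples_per_window: int = 20_000,
    surface: DoubleWell1D | None = None,
) -> tuple[DoubleWell1D, list[UmbrellaWindow]]:
    """24 windows spanning the double well, one force-constant tier."""
    surface = surface if surface is not None else default_double_well()
    centres = np.linspace(0.18, 1.02, 24)[:, None]
    k = units.kj_to_kcal(CANONICAL_1D_FORCE_CONSTANT_KJ)
    stride = 50
    n_steps = int(np.ceil(n_samples_per_window * stride / 0.9))
    params = LangevinParams(
        timestep=2e-5, friction=1.0, n_steps=n_steps, stride=stride, seed=seed
    )
    windows = make_umbrella_campaign(surface, centres, [[k]], params)
    return surface, windows


def canonical_2d_campaign(
    seed: int = 0,
    n_samples_per_window: int = 10_000,
    surface: GaussianBasinMixture | None = None,
) -> tuple[GaussianBasinMixture, list[UmbrellaWindow]]:
    """The 144-window two-tier design on the three-basin surface."""
    surface = surface if surface is not None else three_basin_surface()
    centres = np.column_stack([np.linspace(-1.35, 1.35, 24), np.zeros(24)])
    tiers = [
        [units.kj_to_kcal(k) for k in tier] for tier in CANONICAL_2D_TIERS_KJ
    ]
    stride = 50
    n_steps = int(np.ceil(n_samples_per_window * stride / 0.9))
    params = LangevinParams(
        timestep=1.5e-5, friction=1.0, n_steps=n_steps, stride=stride, seed=seed
    )
    windows = make_umbrella_campaign(surface, centres, tiers, params, n_replicates=3)
    return surface, windows
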