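"""Unit conventions and physical constants.

Internal units everywhere in this package: nm for gate distances, ps for
time, kcal/mol for energies, Kelvin for temperature.  Force constants read
from configs or window manifests are given in kJ/mol/(CV unit)^2 (the
convention of the MD ecosystem the input files come from) and converted on
ingestion with the exact thermochemical calorie, 1 kcal = 4.184 kJ.
"""

import math

KJ_PER_KCAL: float = 4.184
KB_KCAL: float = 1.987204259e-3  # Boltzmann constant, kcal/mol/K
DEFAULT_TEMPERATURE: float = 310.0  # K, physiological
STANDARD_VOLUME_NM3: float = 1.660539  # nm^3 per molecule at 1 M


def kj_to_kcal(x: float) -> float:
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol."""
    return KB_KCAL * temperature


def beta(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse thermal energy 1/kT in mol/kcal."""
    return 1.0 / kt(temperature)


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT ln(10) in kcal/mol — the free-energy cost of one pKa unit."""
    return kt(temperature) * math.log(10.0)
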