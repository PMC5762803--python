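"""Embedded physical constants for PMMA (C5H8O2, density 1.19 g/cm^3).

Mass attenuation coefficients are frozen from standard tabulations
(photoelectric + incoherent; coherent scattering excluded because
forward-scattered photons remain inside the analyzer acceptance and are
not removed from the transmitted beam). Values in cm^2/g versus keV.
"""

from __future__ import annotations

import numpy as np

PMMA_DENSITY_G_CM3 = 1.19

# (energy keV, mu/rho cm^2/g), photoelectric + Compton
_PMMA_MU_RHO_TABLE = np.array(
    [
        (10.0, 3.175534),
        (12.0, 1.851847),
        (14.0, 1.197598),
        (15.0, 0.994183),
        (16.0, 0.840658),
        (17.0, 0.722808),
        (18.0, 0.630969),
        (20.0, 0.500425),
        (22.0, 0.415250),
        (25.0, 0.335483),
        (30.0, 0.266031),
    ]
)

#: refractive index decrement delta of PMMA (dimensionless)
PMMA_DELTA_17KEV = 9.2267e-07
PMMA_DELTA_25KEV = 4.2641e-07


def pmma_mu_rho(energy_kev: float) -> float:
    """Mass attenuation coefficient of PMMA in cm^2/g, log-log interpolated."""
    e = float(energy_kev)
    tab = _PMMA_MU_RHO_TABLE
    if not (tab[0, 0] <= e <= tab[-1, 0]):
        raise ValueError(f"energy {e} keV outside tabulated range")
    return float(np.exp(np.interp(np.log(e), np.log(tab[:, 0]), np.log(tab[:, 1]))))


def pmma_mu_per_mm(energy_kev: float) -> float:
    """Linear attenuation coefficient of PMMA in 1/mm."""
    return pmma_mu_rho(energy_kev) * PMMA_DENSITY_G_CM3 / 10.0


def pmma_transmission(thickness_mm: float, energy_kev: float) -> float:
    """Transmission through a PMMA slab of the given thickness."""
    return float(np.exp(-pmma_mu_per_mm(energy_kev) * thickness_mm))
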