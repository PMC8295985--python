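"""Physical constants and NMR frequency conversions shared across the package.

All energies are handled in J/mol internally; kJ appears only at presentation.
Gyromagnetic ratios are expressed relative to the proton, so a nucleus Larmor
frequency follows directly from the spectrometer's nominal 1H frequency.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23
#: Planck constant, J*s (2019 SI exact value).
H_PLANCK = 6.62607015e-34
#: Molar gas constant, J/(mol*K).
R_GAS = 8.31446
#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15

#: |gamma_X / gamma_1H| for the nuclei handled by the package.
GAMMA_RATIO = {
    "15N": 0.10136767,
    "13C": 0.25145002,
}


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - CELSIUS_OFFSET


def nucleus_frequency_hz(field_mhz: float, nucleus: str) -> float:
    """Larmor frequency (Hz) of ``nucleus`` at a nominal 1H field in MHz."""
    try:
        ratio = GAMMA_RATIO[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}; expected one of {sorted(GAMMA_RATIO)}")
    return field_mhz * 1e6 * ratio


def ppm_to_rad_per_s(delta_ppm: float, field_mhz: float, nucleus: str) -> float:
    """Convert a chemical-shift difference in ppm to angular frequency (rad/s).

    delta_omega = delta_ppm * 1e-6 * 2*pi * nu_nucleus, with nu_nucleus the
    Larmor frequency of the nucleus at the given static field.
    """
    return delta_ppm * 1e-6 * 2.0 * math.pi * nucleus_frequency_hz(field_mhz, nucleus)


def rad_per_s_to_ppm(delta_rad: float, field_mhz: float, nucleus: str) -> float:
    """Inverse of :func:`ppm_to_rad_per_s`."""
    return delta_rad / (1e-6 * 2.0 * math.pi * nucleus_frequency_hz(field_mhz, nucleus))
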