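"""Unit system and physical constants.

The working unit system is the one conventional in coarse-grained normal mode
analysis: lengths in Å, energies in kcal/mol, masses in amu.  Eigenvalues of
the generalized problem K v = λ M v then carry kcal mol⁻¹ amu⁻¹ Å⁻² and
convert to spectroscopic wavenumbers (cm⁻¹) through a single factor.
"""

import math

import scipy.constants as _c

#: Boltzmann constant in kcal mol⁻¹ K⁻¹ (i.e. the molar gas constant in kcal).
KB_KCAL_MOL_K = _c.R / _c.calorie / 1000.0  # ≈ 0.0019872

#: Joules per kcal/mol (per molecule).
_J_PER_KCAL_MOL = _c.calorie * 1000.0 / _c.Avogadro

#: Speed of light in cm/s.
C_CM_S = _c.c * 100.0

#: ω[cm⁻¹] = WAVENUMBER_FACTOR · sqrt(λ) for λ in kcal mol⁻¹ amu⁻¹ Å⁻².
#: sqrt(λ) is converted to angular frequency in s⁻¹ and divided by 2πc.
WAVENUMBER_FACTOR = math.sqrt(
    _J_PER_KCAL_MOL / (_c.atomic_mass * 1e-20)
) / (2.0 * math.pi * C_CM_S)  # ≈ 108.59

#: 1 kcal mol⁻¹ Å⁻³ expressed in GPa (pressure / Young's modulus conversion).
GPA_PER_KCAL_MOL_A3 = _J_PER_KCAL_MOL / 1e-30 / 1e9  # ≈ 6.95

#: Default temperature (K) for thermal amplitudes and B-factor calibration.
DEFAULT_TEMPERATURE = 298.0
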