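"""Physical constants and unit-conversion factors used by the exciton engine.

All engine-facing quantities use a single mixed unit system that is standard
in matrix-method CD work:

* lengths in Å,
* charges in elementary charges (e),
* energies/wavenumbers in cm⁻¹,
* electric transition dipoles in Debye (D),
* magnetic transition dipoles in Bohr magnetons (μB),
* rotational strengths in 10⁻⁴⁰ esu·cm·erg/G (the conventional cgs unit).

Every cross-unit factor lives here so the conversions are auditable in one
place.
"""

from __future__ import annotations

import math

import scipy.constants as _sc

# --- fundamental values (CODATA via scipy) ---------------------------------

#: 1 Debye in e·Å (≈ 0.2082): 1 D = 1e-21/c C·m.
DEBYE_TO_E_ANGSTROM: float = 1e-21 / _sc.c / _sc.e * 1e10

#: e²/(4πε₀ · 1 Å) expressed in cm⁻¹ — the Coulomb prefactor for point
#: charges in e separated by distances in Å (≈ 1.1614e5 cm⁻¹).
COULOMB_CM1_PER_E2_ANGSTROM: float = (
    _sc.e**2 / (4 * math.pi * _sc.epsilon_0 * 1e-10)  # J
    / (_sc.h * _sc.c)  # -> m^-1
    / 100.0  # -> cm^-1
)

#: 1 D·μB in esu·cm·erg/G (≈ 0.9274e-38); dividing by 1e-40 gives the
#: conventional rotational-strength unit.
DEBYE_BOHR_MAGNETON_TO_CGS: float = 1e-18 * (_sc.value("Bohr magneton") * 1e3)

#: D·μB expressed in 10⁻⁴⁰ esu·cm·erg/G (≈ 92.74).
DEBYE_BOHR_MAGNETON_TO_1E40_CGS: float = DEBYE_BOHR_MAGNETON_TO_CGS / 1e-40

#: Conversion for the positional ("R × μ") magnetic term:
#: ν̃ [cm⁻¹] · r [Å] · μ [D] → μB.  One factor of π is applied in the
#: rotational-strength formula, not here.  Numerically 1e-26 erg/G per
#: (cm⁻¹·Å·D) divided by μB in erg/G.
POSITIONAL_MAGNETIC_MUB_PER_CM1_ANGSTROM_DEBYE: float = (
    1e-26 / (_sc.value("Bohr magneton") * 1e3)
)

#: Denominator constant of the Gaussian band-shape formula
#: Δε(ν̃) = Σ_k ν̃ R_k / (BAND_SHAPE_CONSTANT √π Δ_k) exp(−((ν̃−ν̃_k)/Δ_k)²)
#: with R_k in esu·cm·erg/G.
BAND_SHAPE_CONSTANT: float = 2.296e-39

#: Mean residue ellipticity per unit Δε: [θ] = 3298 · Δε.
MRE_PER_DELTA_EPSILON: float = 3298.0

#: nm ↔ cm⁻¹: ν̃ = NM_CM1 / λ.
NM_CM1: float = 1.0e7
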