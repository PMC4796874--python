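"""Physical constants and unit conversions.

All internal units: lengths in Å, charges in elementary charge e, energies in
kcal/mol, temperature in K.  Electrostatic potentials are carried in kT/e at the
problem temperature and converted to kcal/mol only at the energy-reporting
surface, so every conversion happens in exactly one place.
"""

from __future__ import annotations

import math

#: Coulomb constant e^2/(4 pi eps0), kcal mol^-1 Å e^-2.
COULOMB_K = 332.0637

#: Boltzmann constant, kcal mol^-1 K^-1 (1 kT = 0.0019872*T kcal/mol).
KB_KCAL = 0.0019872

#: mol/L -> particles per Å^3.
MOLAR_TO_PER_A3 = 6.02214076e-4


def kt_kcal(temperature: float) -> float:
    """kT in kcal/mol at the given temperature."""
    return KB_KCAL * temperature


def coulomb_kt(temperature: float) -> float:
    """Coulomb constant in units of (kT/e) * Å * e^-1.

    The potential of a charge q (e) at distance r (Å) in uniform relative
    dielectric eps is ``coulomb_kt(T) * q / (eps * r)`` in kT/e.
    """
    return COULOMB_K / kt_kcal(temperature)


def debye_kappa(ionic_strength: float, temperature: float, eps_solvent: float) -> float:
    """Inverse Debye screening length kappa in Å^-1.

    For a 1:1 salt at ionic strength I (mol/L) the linearized screening term is
    eps_s * kappa^2 * phi with kappa^2 = 8 pi C(T) n / eps_s, n the ion number
    density in Å^-3.  At 150 mM in water (eps 80, 298 K) this gives a Debye
    length of ~7.9 Å.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    n = ionic_strength * MOLAR_TO_PER_A3
    return math.sqrt(8.0 * math.pi * coulomb_kt(temperature) * n / eps_solvent)
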