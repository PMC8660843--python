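"""Physical constants (CODATA 2022, via scipy) used across the package.

Everything unit-sensitive is assembled here once, so couplings and rates
share a single source of truth.
"""

from scipy import constants as _c

#: Planck constant, J s
PLANCK_J_S = _c.Planck
#: Reduced Planck constant, J s
HBAR_J_S = _c.hbar
#: Boltzmann constant, J/K
BOLTZMANN_J_K = _c.Boltzmann
#: Speed of light, m/s
C_M_S = _c.speed_of_light

#: 1 cm^-1 in Joules  (E = h c / lambda)
WAVENUMBER_TO_J = _c.Planck * _c.speed_of_light * 100.0
#: 1 eV in Joules
EV_TO_J = _c.electron_volt

#: Hartree energy expressed in cm^-1
HARTREE_TO_WAVENUMBER = _c.physical_constants["hartree-inverse meter relationship"][0] / 100.0
#: Bohr radius in Angstrom
BOHR_TO_ANGSTROM = _c.physical_constants["Bohr radius"][0] * 1e10

#: Coulomb-interaction constant converting  e^2 / Angstrom  to  cm^-1.
#:
#: One Hartree is e^2/(4 pi eps0 a0), so  e^2/(4 pi eps0 * 1 A)  equals
#: Hartree * (a0 / 1 A); expressed in wavenumbers this is the product below
#: (~1.16140e5 cm^-1 A / e^2).
COULOMB_E2_ANGSTROM_TO_WAVENUMBER = HARTREE_TO_WAVENUMBER * BOHR_TO_ANGSTROM

#: Bondi van der Waals radii, Angstrom, for the elements met in pigments.
BONDI_VDW_RADII_A = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "MG": 1.73,
}
#: Fallback vdW radius for elements not tabulated above.
DEFAULT_VDW_RADIUS_A = 1.70
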