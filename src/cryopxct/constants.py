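"""Physical constants used throughout the package.

These are fixed module-level constants, never mutated at run time.
"""

#: Classical electron radius, m.
R_E_M = 2.8179403e-15

#: Classical electron radius, Å (convenience for electron densities in e/Å³).
R_E_A = R_E_M * 1e10

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: hc product for X-ray energy/wavelength conversion, m·keV.
HC_M_KEV = 1.23984193e-9

#: Molar mass per electron for soft biological matter (water/lipid/protein/
#: chromatin mixture), g/mol.  Converts electron density to mass density.
MOLAR_MASS_PER_ELECTRON_G_MOL = 1.86

#: Electron-volt, J (for dose calculations; 1 keV = 1e3 eV).
EV_J = 1.602176634e-19


def wavelength_m(photon_energy_kev: float) -> float:
    """X-ray wavelength λ = hc/E in metres for a photon energy in keV."""
    if photon_energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {photon_energy_kev}")
    return HC_M_KEV / photon_energy_kev
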