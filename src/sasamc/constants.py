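"""Physical constants and shipped model defaults.

Units used throughout the package: lengths in Å, energies in kJ/mol,
temperatures in K, molar concentrations in mol/L (M), molalities in mol/kg.
"""

#: Gas constant, kJ/(mol K).
R_KJ = 8.314462618e-3

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Molar mass of water, kg/mol.
M1_WATER = 0.0180153

#: Molar mass of caffeine, g/mol.
CAFFEINE_MOLAR_MASS = 194.19

#: Default simulation temperature, K.
T_DEFAULT = 298.15

#: Temperature of the osmometry experiments and the thermodynamic model, K.
T_VPO = 310.15

#: Calibrated microscopic surface tension of the attractive (heterocycle)
#: beads, kJ/(mol Å²).
GAMMA_CALIBRATED = 0.0572

#: WCA well depth used during calibration, kJ/mol.
WCA_EPSILON_DEFAULT = 0.5

#: Water-probe radius, Å.
PROBE_RADIUS_DEFAULT = 1.4

#: Scale factor applied to the bare group diameter when building the
#: WCA core size, σ_i = WCA_CORE_SCALE · 2·(R_i − r_probe).  It sets how
#: deeply beads may interpenetrate the probe-inflated SASA spheres and
#: thereby the softness and depth of the stacking attraction; the value
#: is fixed once against the published salt-free structural validation
#: of the calibrated model, the caffeine-caffeine Kirkwood-Buff integral
#: G22 ≈ 20×10³ Å³.
WCA_CORE_SCALE = 1.08

#: Salt-specific transfer-free-energy coefficients, kJ/(mol Å² M),
#: obtained by matching grand-canonical excess chemical potentials to
#: solubility-derived data at caffeine molar activity 0.026.
TFE_BY_SALT = {
    "Na2SO4": 0.0178,
    "NaCl": 0.003,
    "NaBr": -0.001,
    "NaSCN": -0.008,
    "NaClO4": -0.0125,
}

#: Ions per formula unit for the salts considered.
NU_BY_SALT = {"Na2SO4": 3, "NaCl": 2, "NaBr": 2, "NaSCN": 2, "NaClO4": 2}


def kT(temperature: float) -> float:
    """Thermal energy k_B*T*N_A in kJ/mol."""
    return R_KJ * temperature


def molar_to_number_density(c_molar: float) -> float:
    """Convert mol/L to number per Å³."""
    return c_molar * AVOGADRO * 1e-27


def number_density_to_molar(rho: float) -> float:
    """Convert number per Å³ to mol/L."""
    return rho / (AVOGADRO * 1e-27)
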