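"""Physical constants and unit conversions.

Internal unit system (LAMMPS "real"-style):

* length   — ångström (Å)
* time     — femtosecond (fs)
* mass     — dalton (Da)
* energy   — kcal/mol

Velocities are Å/fs, forces kcal/mol/Å.  Interaction strengths are
frequently quoted in units of the thermal energy kT at 310 K, where
1 kT ≈ 0.616 kcal/mol.
"""

# Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_PER_MOL_K = 0.0019872

#: default simulation temperature, K
DEFAULT_TEMPERATURE = 310.0

#: 1 kcal/mol expressed in Da Å^2 fs^-2 (the "mechanical" energy unit of
#: the internal unit system).  1 Da Å^2/fs^2 = 1e7 J/mol, so the factor is
#: 4184/1e7.
KCAL_PER_MOL_TO_DA_A2_FS2 = 4.184e-4


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kT in kcal/mol at the given temperature (K)."""
    return KB_KCAL_PER_MOL_K * temperature


def kt_to_kcal(value_kt: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy expressed in kT units to kcal/mol."""
    return value_kt * thermal_energy(temperature)


def kcal_to_kt(value_kcal: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in kcal/mol to kT units."""
    return value_kcal / thermal_energy(temperature)
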