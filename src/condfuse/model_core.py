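"""Force-field parameters and the four pair/angle potentials.

The model is a two-flavor sticker-spacer bead-spring polymer:

* harmonic backbone springs,  E = Kb (R - R0)^2
* bending stiffness,          E = kappa (1 - cos theta)
* truncated Lennard-Jones between all non-excluded bead pairs,
  E = 4 Ens [(sigma/r)^12 - (sigma/r)^6]   for r < Rmax
* a shifted-harmonic "specific" well between a bonded sticker pair,
  E = Es/(R0b - Rcut)^2 [(R - R0b)^2 - (Rcut - R0b)^2]  for R < Rcut

All energies are stored in kcal/mol; configuration files may quote Es and
Ens in kT, which is converted once at load time (T = 310 K by default).
Each ``*_energy`` function has a matching ``*_dEdR`` giving the scalar
derivative with respect to the distance (or angle), from which Cartesian
forces follow by the chain rule.  Functions accept scalars or numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt_to_kcal


@dataclass(frozen=True)
class ForceField:
    """All interaction constants plus the kinetic-bond parameters.

    Energies in kcal/mol, distances in Å.  The defaults correspond to the
    reference parameterization: Kb = 3 kcal/mol/Å², R0 = 10 Å, kappa = 2
    kcal/mol, sigma = 10 Å, LJ cutoff 2.5 sigma, sticker-bond rest
    distance 1.122 sigma with break/formation cutoff R0 + 1.5 Å, and
    deterministic bond moves (p_on = p_off = 1) attempted every 20 steps.
    """

    Kb: float = 3.0
    R0_backbone: float = 10.0
    kappa: float = 2.0
    sigma: float = 10.0
    Rmax_LJ: float = 25.0
    Es: float = 6.16
    Ens: float = 0.3 * 0.616
    R0_bond: float = 11.22
    Rcut_bond: float = 12.72
    p_on: float = 1.0
    p_off: float = 1.0
    bond_update_interval: int = 20
    lj_shift: bool = False

    def __post_init__(self) -> None:
        if not (self.Rcut_bond > self.R0_bond > 0):
            raise ValueError("require Rcut_bond > R0_bond > 0")
        if not (self.Rmax_LJ > self.sigma > 0):
            raise ValueError("require Rmax_LJ > sigma > 0")
        if self.Es < 0 or self.Ens < 0:
            raise ValueError("well depths Es, Ens must be non-negative")
        if not (0.0 <= self.p_on <= 1.0 and 0.0 <= self.p_off <= 1.0):
            raise ValueError("p_on, p_off must lie in [0, 1]")
        if self.bond_update_interval < 1:
            raise ValueError("bond_update_interval must be a positive integer")
        if self.Kb < 0 or self.kappa < 0 or self.R0_backbone <= 0:
            raise ValueError("invalid backbone parameters")

    @classmethod
    def from_kt(
        cls,
        Es_kt: float,
        Ens_kt: float,
        temperature: float = DEFAULT_TEMPERATURE,
        **kwargs,
    ) -> "ForceField":
        """Build a force field with Es and Ens quoted in kT units."""
        return cls(
            Es=kt_to_kcal(Es_kt, temperature),
            Ens=kt_to_kcal(Ens_kt, temperature),
            **kwargs,
        )

    def with_(self, **kwargs) -> "ForceField":
        return replace(self, **kwargs)

    @property
    def interaction_cutoff(self) -> float:
        """Largest distance at which any nonbonded interaction acts."""
        return max(self.Rmax_LJ, self.Rcut_bond)


@dataclass(frozen=True)
class ThermoParams:
    """Langevin thermostat / integrator settings.

    ``damp`` is the friction *time*: the drag force is -(mass/damp) v, so
    small damp means a viscous medium.
    """

    T: float = DEFAULT_TEMPERATURE
    damp: float = 500.0
    dt: float = 30.0
    mass: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.T, self.damp, self.dt, self.mass) <= 0:
            raise ValueError("all thermostat parameters must be positive")


# ---------------------------------------------------------------------------
# backbone


def backbone_energy(R, ff: ForceField):
    """Harmonic backbone stretching energy Kb (R - R0)^2."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("interbead distance must be positive")
    return ff.Kb * (R - ff.R0_backbone) ** 2


def backbone_dEdR(R, ff: ForceField):
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("interbead distance must be positive")
    return 2.0 * ff.Kb * (R - ff.R0_backbone)


# ---------------------------------------------------------------------------
# bending
#
# theta is the deflection angle between successive bond vectors: a straight
# chain has theta = 0 and zero energy, a hairpin has theta = pi and energy
# 2 kappa.  This convention is recorded in run metadata.


def bending_energy(theta, ff: ForceField):
    """Bending energy kappa (1 - cos theta), theta in radians, [0, pi]."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi + 1e-12)):
        raise ValueError("bending angle must lie in [0, pi]")
    return ff.kappa * (1.0 - np.cos(theta))


def bending_dEdtheta(theta, ff: ForceField):
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi + 1e-12)):
        raise ValueError("bending angle must lie in [0, pi]")
    return ff.kappa * np.sin(theta)


# ---------------------------------------------------------------------------
# nonspecific Lennard-Jones


def lj_energy(r, ff: ForceField):
    """Truncated 12-6 LJ energy; exactly zero at and beyond Rmax_LJ.

    Plain truncation by default (no energy shift at the cutoff); set
    ``lj_shift`` on the force field to subtract E(Rmax) inside the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ separation must be positive (r=0 is singular)")
    sr6 = (ff.sigma / r) ** 6
    e = 4.0 * ff.Ens * (sr6 * sr6 - sr6)
    if ff.lj_shift:
        sc6 = (ff.sigma / ff.Rmax_LJ) ** 6
        e = e - 4.0 * ff.Ens * (sc6 * sc6 - sc6)
    return np.where(r < ff.Rmax_LJ, e, 0.0)


def lj_dEdr(r, ff: ForceField):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ separation must be positive (r=0 is singular)")
    sr6 = (ff.sigma / r) ** 6
    d = 4.0 * ff.Ens * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return np.where(r < ff.Rmax_LJ, d, 0.0)


# ---------------------------------------------------------------------------
# specific sticker bond (shifted harmonic)


def specific_bond_energy(R, ff: ForceField):
    """Shifted-harmonic sticker-bond energy.

    E(R) = [Es / (R0b - Rcut)^2] [(R - R0b)^2 - (Rcut - R0b)^2] for
    R < Rcut; zero at R = Rcut and for all R beyond it.  The well depth is
    -Es at the rest distance R0b.  Only applies to a currently bonded
    sticker pair.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("intersticker distance must be non-negative")
    a = ff.Es / (ff.R0_bond - ff.Rcut_bond) ** 2
    w2 = (ff.Rcut_bond - ff.R0_bond) ** 2
    e = a * ((R - ff.R0_bond) ** 2 - w2)
    return np.where(R < ff.Rcut_bond, e, 0.0)


def specific_bond_dEdR(R, ff: ForceField):
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("intersticker distance must be non-negative")
    a = ff.Es / (ff.R0_bond - ff.Rcut_bond) ** 2
    return np.where(R < ff.Rcut_bond, 2.0 * a * (R - ff.R0_bond), 0.0)


# ---------------------------------------------------------------------------
# Cartesian pair forces


def pair_force(kind: str, rvec, ff: ForceField):
    """Force on particle i of a pair (i, j) with separation rvec = ri - rj.

    ``kind`` is one of "backbone", "lj", "bond".  Returns -dE/dri, the
    analytic negative gradient; the force on j is the negation.
    """
    rvec = np.asarray(rvec, dtype=float)
    r = np.linalg.norm(rvec, axis=-1)
    deriv = {
        "backbone": backbone_dEdR,
        "lj": lj_dEdr,
        "bond": specific_bond_dEdR,
    }[kind](r, ff)
    with np.errstate(invalid="ignore"):
        unit = rvec / np.expand_dims(np.where(r > 0, r, 1.0), -1)
    return -np.expand_dims(deriv, -1) * unit
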