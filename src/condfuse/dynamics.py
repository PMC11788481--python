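"""Langevin dynamics engine: forces, BAOAB integrator, run loop.

Forces are the sum of the four model potentials (backbone springs,
bending, truncated LJ over non-excluded neighbor pairs, shifted-harmonic
sticker bonds) plus any bias hooks.  While a sticker pair is bonded its
LJ interaction is turned off and replaced by the specific-bond well; it
resumes when the bond breaks.

The integrator is a BAOAB Langevin splitting with friction coefficient
m/damp and Gaussian noise obeying fluctuation-dissipation at the target
temperature, stable at the default dt = 30 fs for 1000 Da beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bond_kinetics import EventLog, update_bonds
from .constants import KB_KCAL_PER_MOL_K, KCAL_PER_MOL_TO_DA_A2_FS2
from .model_core import ForceField, ThermoParams
from .neighbors import NeighborList
from .state import SystemState, min_image


class NumericalInstabilityError(RuntimeError):
    pass


def _accumulate(F: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    n = len(F)
    for d in range(3):
        F[:, d] += np.bincount(idx, weights=contrib[:, d], minlength=n)


class ForceContext:
    """Caches topology-derived interaction lists and the neighbor list.

    Reuse one context for a whole run; construct a new one whenever the
    topology (chain membership) changes.
    """

    def __init__(self, state: SystemState, ff: ForceField,
                 skin: float = 3.0, exclusion_bonds: int = 2,
                 use_compiled: bool | None = None):
        from . import _kernels

        self.ff = ff
        self.exclusion_bonds = exclusion_bonds
        self.backbone = state.backbone_bonds()
        self.triplets = state.bending_triplets()
        self.nlist = NeighborList(ff.interaction_cutoff, skin)
        self.nlist.build(state, exclusion_bonds)
        if use_compiled is None:
            use_compiled = _kernels.HAVE_NUMBA
        self.use_compiled = use_compiled and _kernels.HAVE_NUMBA
        self._bonded_cache: np.ndarray | None = None
        self._bonded_version = -1

    def _bonded_pairs(self, state: SystemState) -> np.ndarray:
        # registry mutations bump state.bond_version (see update_bonds)
        if self._bonded_version != state.bond_version or self._bonded_cache is None:
            self._bonded_cache = state.bonded_pairs()
            self._bonded_version = state.bond_version
        return self._bonded_cache

    def compute(self, state: SystemState, bias_hooks=(), force_cap: float | None = None):
        """Per-bead forces (kcal/mol/Å) and the energy breakdown."""
        if self.use_compiled:
            F, energies = self._compute_compiled(state)
        else:
            F, energies = self._compute_numpy(state)

        for hook in bias_hooks:
            fb, eb = hook.bead_forces(state)
            F += fb
            energies["E_bias"] += eb

        if not np.all(np.isfinite(F)):
            bad = np.flatnonzero(~np.all(np.isfinite(F), axis=1))
            raise NumericalInstabilityError(
                f"non-finite force on bead(s) {bad[:5].tolist()} at step {state.step}")
        if force_cap is not None:
            norm = np.sqrt(np.einsum("ij,ij->i", F, F))
            over = norm > force_cap
            if np.any(over):
                F[over] *= (force_cap / norm[over])[:, None]
        return F, energies

    def _compute_compiled(self, state: SystemState):
        from . import _kernels

        ff = self.ff
        box = state.box_length
        pos = state.positions
        F = np.zeros((state.n_beads, 3))
        energies = {"E_backbone": 0.0, "E_bend": 0.0, "E_contact": 0.0,
                    "E_bond": 0.0, "E_bias": 0.0}
        if len(self.backbone):
            energies["E_backbone"] = _kernels.backbone_forces(
                pos, self.backbone, box, ff.Kb, ff.R0_backbone, F)
        if len(self.triplets) and ff.kappa != 0.0:
            energies["E_bend"] = _kernels.bending_forces(
                pos, self.triplets, box, ff.kappa, F)
        self.nlist.ensure_current(state, self.exclusion_bonds)
        if len(self.nlist.pairs) and ff.Ens > 0.0:
            e_shift = 0.0
            if ff.lj_shift:
                sc6 = (ff.sigma / ff.Rmax_LJ) ** 6
                e_shift = 4.0 * ff.Ens * (sc6 * sc6 - sc6)
            energies["E_contact"] = _kernels.lj_forces(
                pos, self.nlist.pairs, self.nlist.excluded,
                state.bond_partner, box, ff.sigma ** 2, ff.Ens,
                ff.Rmax_LJ ** 2, e_shift, F)
        bonded = self._bonded_pairs(state)
        if len(bonded) and ff.Es > 0.0:
            a_coef = ff.Es / (ff.R0_bond - ff.Rcut_bond) ** 2
            energies["E_bond"] = _kernels.bond_forces(
                pos, bonded, box, a_coef, ff.R0_bond, ff.Rcut_bond, F)
        return F, energies

    def _compute_numpy(self, state: SystemState):
        ff = self.ff
        box = state.box_length
        pos = state.positions
        n = state.n_beads
        F = np.zeros((n, 3))
        energies = {"E_backbone": 0.0, "E_bend": 0.0, "E_contact": 0.0,
                    "E_bond": 0.0, "E_bias": 0.0}

        # backbone springs
        bb = self.backbone
        if len(bb):
            i, j = bb[:, 0], bb[:, 1]
            dr = min_image(pos[i] - pos[j], box)
            r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
            energies["E_backbone"] = float(np.sum(ff.Kb * (r - ff.R0_backbone) ** 2))
            fmag = -2.0 * ff.Kb * (r - ff.R0_backbone) / r
            fvec = fmag[:, None] * dr
            _accumulate(F, i, fvec)
            _accumulate(F, j, -fvec)

        # bending
        trip = self.triplets
        if len(trip) and ff.kappa != 0.0:
            a, b, c = trip[:, 0], trip[:, 1], trip[:, 2]
            b1 = min_image(pos[b] - pos[a], box)
            b2 = min_image(pos[c] - pos[b], box)
            n1 = np.sqrt(np.einsum("ij,ij->i", b1, b1))
            n2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
            cos = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
            np.clip(cos, -1.0, 1.0, out=cos)
            energies["E_bend"] = float(np.sum(ff.kappa * (1.0 - cos)))
            inv12 = 1.0 / (n1 * n2)
            dcos_db1 = b2 * inv12[:, None] - b1 * (cos / n1 ** 2)[:, None]
            dcos_db2 = b1 * inv12[:, None] - b2 * (cos / n2 ** 2)[:, None]
            fa = -ff.kappa * dcos_db1
            fc = ff.kappa * dcos_db2
            _accumulate(F, a, fa)
            _accumulate(F, c, fc)
            _accumulate(F, b, -(fa + fc))

        # nonspecific LJ over neighbor pairs
        self.nlist.ensure_current(state, self.exclusion_bonds)
        pairs = self.nlist.pairs
        if len(pairs) and ff.Ens > 0.0:
            keep = ~self.nlist.excluded
            i, j = pairs[keep, 0], pairs[keep, 1]
            # LJ is suppressed between a currently bonded sticker pair
            not_bonded = state.bond_partner[i] != j
            i, j = i[not_bonded], j[not_bonded]
            dr = min_image(pos[i] - pos[j], box)
            r2 = np.einsum("ij,ij->i", dr, dr)
            within = r2 < ff.Rmax_LJ ** 2
            i, j, dr, r2 = i[within], j[within], dr[within], r2[within]
            if len(i):
                sr6 = (ff.sigma ** 2 / r2) ** 3
                e = 4.0 * ff.Ens * (sr6 * sr6 - sr6)
                if ff.lj_shift:
                    sc6 = (ff.sigma / ff.Rmax_LJ) ** 6
                    e = e - 4.0 * ff.Ens * (sc6 * sc6 - sc6)
                energies["E_contact"] = float(np.sum(e))
                fmag_over_r = 4.0 * ff.Ens * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
                fvec = fmag_over_r[:, None] * dr
                _accumulate(F, i, fvec)
                _accumulate(F, j, -fvec)

        # specific sticker bonds
        bonded = self._bonded_pairs(state)
        if len(bonded) and ff.Es > 0.0:
            i, j = bonded[:, 0], bonded[:, 1]
            dr = min_image(pos[i] - pos[j], box)
            r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
            a_coef = ff.Es / (ff.R0_bond - ff.Rcut_bond) ** 2
            w2 = (ff.Rcut_bond - ff.R0_bond) ** 2
            inside = r < ff.Rcut_bond
            e = np.where(inside, a_coef * ((r - ff.R0_bond) ** 2 - w2), 0.0)
            energies["E_bond"] = float(np.sum(e))
            fmag = np.where(inside, -2.0 * a_coef * (r - ff.R0_bond) / r, 0.0)
            fvec = fmag[:, None] * dr
            _accumulate(F, i, fvec)
            _accumulate(F, j, -fvec)

        return F, energies


def thermalize_velocities(state: SystemState, thermo: ThermoParams,
                          rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann velocities at the thermostat temperature."""
    kt_mech = KB_KCAL_PER_MOL_K * thermo.T * KCAL_PER_MOL_TO_DA_A2_FS2
    state.velocities[:] = rng.normal(
        0.0, np.sqrt(kt_mech / thermo.mass), size=state.velocities.shape)


class LangevinIntegrator:
    """BAOAB splitting of underdamped Langevin dynamics.

    Friction force is -(mass/damp) v; the O-step uses the exact
    Ornstein-Uhlenbeck update so fluctuation-dissipation holds for any
    dt/damp ratio.
    """

    def __init__(self, thermo: ThermoParams, rng: np.random.Generator):
        self.thermo = thermo
        self.rng = rng
        dt, damp = thermo.dt, thermo.damp
        self._c1 = np.exp(-dt / damp)
        kt_mech = KB_KCAL_PER_MOL_K * thermo.T * KCAL_PER_MOL_TO_DA_A2_FS2
        self._vsig = np.sqrt((1.0 - self._c1 ** 2) * kt_mech / thermo.mass)
        self._ftm = KCAL_PER_MOL_TO_DA_A2_FS2 / thermo.mass  # F -> acceleration
        self._half_dt = 0.5 * dt

    def step(self, state: SystemState, forces: np.ndarray, force_fn):
        """Advance one step; returns the forces at the new positions."""
        v, x = state.velocities, state.positions
        v += (self._half_dt * self._ftm) * forces            # B
        x += self._half_dt * v                               # A
        v *= self._c1                                        # O
        v += self._vsig * self.rng.standard_normal(v.shape)
        x += self._half_dt * v                               # A
        new_forces, energies = force_fn(state)
        v += (self._half_dt * self._ftm) * new_forces        # B
        state.step += 1
        return new_forces, energies


@dataclass
class Frame:
    step: int
    positions: np.ndarray
    bonds: np.ndarray


@dataclass
class RunResult:
    state: SystemState
    frames: list = field(default_factory=list)
    metrics: pd.DataFrame = None
    event_log: EventLog = None


def run(
    state: SystemState,
    ff: ForceField,
    n_steps: int,
    thermo: ThermoParams | None = None,
    seed: int | np.random.Generator = 0,
    bias=None,
    bond_updates: bool = True,
    snapshot_every: int | None = None,
    metrics_every: int | None = None,
    event_log: EventLog | None = None,
    force_cap: float | None = None,
    exclusion_bonds: int = 2,
    skin: float = 3.0,
    pair_order: str = "nearest",
    wrap_every: int = 0,
) -> RunResult:
    """Advance the system ``n_steps`` with all hooks at exact cadences.

    Bond kinetics run every ``ff.bond_update_interval`` steps (when
    ``bond_updates``); a metadynamics ``bias`` object contributes forces
    every step and deposits hills at its own pace.  Snapshots store
    positions and the bond pair list.  Deterministic for a fixed seed.

    Coordinates are left unwrapped by default (pair interactions always
    use minimum image) so that cluster-level collective variables remain
    continuous; pass ``wrap_every`` to fold them periodically.
    """
    thermo = thermo or ThermoParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if event_log is None:
        event_log = EventLog()
    ctx = ForceContext(state, ff, skin=skin, exclusion_bonds=exclusion_bonds)
    hooks = [bias] if bias is not None else []

    def force_fn(s):
        return ctx.compute(s, bias_hooks=hooks, force_cap=force_cap)

    integrator = LangevinIntegrator(thermo, rng)
    forces, energies = force_fn(state)
    frames: list[Frame] = []
    rows: list[dict] = []

    def record_metrics(energies):
        row = {"step": state.step, **energies}
        row["E_pot"] = sum(energies[k] for k in
                           ("E_backbone", "E_bend", "E_contact", "E_bond"))
        row["T_kin"] = state.kinetic_temperature(thermo.mass)
        row["n_bonds"] = int(np.count_nonzero(state.bond_partner >= 0) // 2)
        if bias is not None:
            row["cv"] = bias.cv_value(state)
        rows.append(row)

    def record_frame():
        frames.append(Frame(state.step, state.positions.copy(),
                            state.bonded_pairs()))

    if snapshot_every:
        record_frame()
    if metrics_every:
        record_metrics(energies)

    interval = ff.bond_update_interval
    for _ in range(n_steps):
        forces, energies = integrator.step(state, forces, force_fn)
        step = state.step
        if bond_updates and step % interval == 0:
            update_bonds(state, ff, rng, log=event_log, pair_order=pair_order)
        if bias is not None and bias.due(step):
            bias.deposit_from_state(state)
        if wrap_every and step % wrap_every == 0:
            state.wrap()
        if snapshot_every and step % snapshot_every == 0:
            record_frame()
        if metrics_every and step % metrics_every == 0:
            record_metrics(energies)

    metrics = pd.DataFrame(rows) if rows else pd.DataFrame()
    return RunResult(state=state, frames=frames, metrics=metrics,
                     event_log=event_log)
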