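"""Reversible, saturating sticker-bond kinetics.

Complementary stickers (flavor A with flavor B) within the capture radius
``Rcut_bond`` form a bond with probability ``p_on``; a bonded pair whose
separation has reached or exceeded ``Rcut_bond`` breaks with probability
``p_off``.  Each sticker holds at most one bond at a time (valency 1), so
formation saturates.  Bond moves are attempted only every
``bond_update_interval`` integration steps, which gives newly formed
bonds time to relax into the harmonic well; with p_on = p_off = 1 the
kinetics are purely distance-triggered and the mean bond lifetime grows
as exp(Es/kT) (Arrhenius escape over the Es-deep well).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_core import ForceField
from .state import FLAVOR_A, FLAVOR_B, SystemState, min_image


@dataclass
class EventLog:
    """Append-only log of bond formation and break events."""

    steps: list = field(default_factory=list)
    events: list = field(default_factory=list)      # "form" | "break"
    bead_i: list = field(default_factory=list)
    bead_j: list = field(default_factory=list)
    lifetimes: list = field(default_factory=list)   # steps; -1 for "form"

    def record(self, step: int, event: str, i: int, j: int, lifetime: int = -1) -> None:
        self.steps.append(step)
        self.events.append(event)
        self.bead_i.append(min(i, j))
        self.bead_j.append(max(i, j))
        self.lifetimes.append(lifetime)

    @property
    def n_breaks(self) -> int:
        return self.events.count("break")

    @property
    def n_forms(self) -> int:
        return self.events.count("form")

    def break_steps(self) -> np.ndarray:
        return np.array([s for s, e in zip(self.steps, self.events) if e == "break"],
                        dtype=np.int64)

    def break_lifetimes(self) -> np.ndarray:
        return np.array([lt for lt, e in zip(self.lifetimes, self.events) if e == "break"],
                        dtype=np.int64)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"step": self.steps, "event": self.events,
             "i": self.bead_i, "j": self.bead_j, "lifetime": self.lifetimes}
        )


def validate_registry(state: SystemState) -> None:
    """Assert the three registry invariants: symmetry, valency 1,
    heterotypic partners only.  Raises AssertionError on violation."""
    partner = state.bond_partner
    bonded = np.flatnonzero(partner >= 0)
    assert np.all(partner[partner[bonded]] == bonded), "registry not symmetric"
    pairs = state.bonded_pairs()
    if len(pairs):
        fi, fj = state.flavor[pairs[:, 0]], state.flavor[pairs[:, 1]]
        assert np.all(fi + fj == FLAVOR_A + FLAVOR_B) and np.all(fi != fj), \
            "homotypic or spacer bond in registry"


def _candidate_pairs(state: SystemState, rcut: float) -> tuple[np.ndarray, np.ndarray]:
    """Unbonded complementary sticker pairs within rcut, with distances."""
    free = np.flatnonzero(state.sticker_mask & (state.bond_partner < 0))
    if len(free) < 2:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    pos = np.mod(state.positions[free], state.box_length)
    if len(free) <= 32:
        ii, jj = np.triu_indices(len(free), k=1)
        pairs = np.column_stack([ii, jj])
    else:
        tree = cKDTree(pos, boxsize=state.box_length)
        pairs = tree.query_pairs(rcut, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty((0, 2), dtype=np.int64), np.empty(0)
    gi, gj = free[pairs[:, 0]], free[pairs[:, 1]]
    hetero = state.flavor[gi] != state.flavor[gj]
    gi, gj = gi[hetero], gj[hetero]
    dr = min_image(state.positions[gi] - state.positions[gj], state.box_length)
    dist = np.linalg.norm(dr, axis=1)
    close = dist < rcut
    return np.column_stack([gi[close], gj[close]]), dist[close]


def update_bonds(
    state: SystemState,
    ff: ForceField,
    rng: np.random.Generator,
    log: EventLog | None = None,
    pair_order: str = "nearest",
) -> None:
    """One bond-kinetics pass: break stretched bonds, then form new ones.

    Phase 1 breaks every bonded pair at separation >= Rcut_bond with
    probability p_off.  Phase 2 enumerates unbonded complementary sticker
    pairs within Rcut_bond and bonds them greedily — nearest pair first
    (or in random order with ``pair_order="random"``) — each with
    probability p_on, skipping stickers claimed earlier in the pass.
    """
    partner = state.bond_partner
    formed = state.bond_formed_step
    state.bond_version += 1

    # phase 1: break
    pairs = state.bonded_pairs()
    if len(pairs):
        dr = state.displacement(pairs[:, 0], pairs[:, 1])
        stretched = np.linalg.norm(dr, axis=1) >= ff.Rcut_bond
        if ff.p_off >= 1.0:
            breaking = stretched
        else:
            breaking = stretched & (rng.random(len(pairs)) < ff.p_off)
        for i, j in pairs[breaking]:
            partner[i] = partner[j] = -1
            if log is not None:
                log.record(state.step, "break", int(i), int(j),
                           lifetime=int(state.step - formed[i]))

    # phase 2: form
    cand, dist = _candidate_pairs(state, ff.Rcut_bond)
    if len(cand) == 0:
        return
    if pair_order == "nearest":
        order = np.argsort(dist, kind="stable")
    elif pair_order == "random":
        order = rng.permutation(len(cand))
    else:
        raise ValueError(f"unknown pair_order {pair_order!r}")
    accept = (np.ones(len(cand), dtype=bool) if ff.p_on >= 1.0
              else rng.random(len(cand)) < ff.p_on)
    for k in order:
        if not accept[k]:
            continue
        i, j = cand[k]
        if partner[i] >= 0 or partner[j] >= 0:
            continue  # claimed earlier in this pass (valency 1)
        partner[i], partner[j] = j, i
        formed[i] = formed[j] = state.step
        if log is not None:
            log.record(state.step, "form", int(i), int(j))


def mean_bond_lifetime(log: EventLog) -> float:
    """Arithmetic mean of logged bond lifetimes in steps.

    Returns NaN (flagged undefined, not an exception) when no break event
    has been logged yet.
    """
    lifetimes = log.break_lifetimes()
    if len(lifetimes) == 0:
        return float("nan")
    return float(np.mean(lifetimes))
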