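"""System state container: coordinates, topology, flavors, bond registry.

Flavors are encoded as small integers: 0 = spacer, 1 = flavor "A"
(red), 2 = flavor "B" (cyan).  Stickers of flavor A bond only with
flavor B and vice versa; spacers never bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPACER = 0
FLAVOR_A = 1
FLAVOR_B = 2

FLAVOR_CODES = {"spacer": SPACER, "A": FLAVOR_A, "B": FLAVOR_B}
FLAVOR_NAMES = {v: k for k, v in FLAVOR_CODES.items()}


def min_image(dr: np.ndarray, box_length: float) -> np.ndarray:
    """Minimum-image convention displacement for a cubic periodic box."""
    return dr - box_length * np.round(dr / box_length)


def center_bead_index(n_beads: int) -> int:
    """0-based index of the bead taken as the chain "center".

    The 17th bead (1-based) for the standard 35-bead chain; generally the
    ``n//2``-th bead 1-based, which reduces to bead 17 at n = 35.
    """
    return max(0, n_beads // 2 - 1) if n_beads > 1 else 0


@dataclass
class SystemState:
    """Positions, velocities and topology of every bead.

    ``chain_id`` is the 0-based chain each bead belongs to,
    ``bead_index`` the 0-based position of the bead within its chain.
    Beads of one chain are stored contiguously in backbone order.
    """

    positions: np.ndarray          # (N, 3) Å
    velocities: np.ndarray         # (N, 3) Å/fs
    box_length: float              # Å
    chain_id: np.ndarray           # (N,) int
    bead_index: np.ndarray         # (N,) int
    flavor: np.ndarray             # (N,) int8
    step: int = 0
    bond_partner: np.ndarray = None   # (N,) int: partner bead id or -1
    bond_formed_step: np.ndarray = None  # (N,) int: step the current bond formed
    bond_version: int = 0             # bumped on every registry mutation

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        n = len(self.positions)
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
        self.bead_index = np.asarray(self.bead_index, dtype=np.int64)
        self.flavor = np.asarray(self.flavor, dtype=np.int8)
        if self.bond_partner is None:
            self.bond_partner = np.full(n, -1, dtype=np.int64)
        if self.bond_formed_step is None:
            self.bond_formed_step = np.zeros(n, dtype=np.int64)
        if not (len(self.velocities) == len(self.chain_id)
                == len(self.bead_index) == len(self.flavor)
                == len(self.bond_partner) == n):
            raise ValueError("inconsistent array lengths in SystemState")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")

    # -- basic queries ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return 0 if self.n_beads == 0 else int(self.chain_id.max()) + 1

    @property
    def sticker_mask(self) -> np.ndarray:
        return self.flavor != SPACER

    def chain_lengths(self) -> np.ndarray:
        return np.bincount(self.chain_id, minlength=self.n_chains)

    def chain_center_ids(self) -> np.ndarray:
        """Bead id of the center bead of every chain (17th bead of a 35-mer)."""
        lengths = self.chain_lengths()
        starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        return starts + np.array([center_bead_index(n) for n in lengths])

    # -- topology-derived interaction lists -------------------------------
    def backbone_bonds(self) -> np.ndarray:
        """(B, 2) bead-id pairs joined by backbone springs."""
        same_chain = self.chain_id[:-1] == self.chain_id[1:]
        consecutive = self.bead_index[1:] == self.bead_index[:-1] + 1
        i = np.flatnonzero(same_chain & consecutive)
        return np.column_stack([i, i + 1])

    def bending_triplets(self) -> np.ndarray:
        """(A, 3) bead-id triplets (i-1, i, i+1) along each chain."""
        bonds = self.backbone_bonds()
        if len(bonds) < 2:
            return np.empty((0, 3), dtype=np.int64)
        chained = bonds[:-1, 1] == bonds[1:, 0]
        first = bonds[:-1][chained]
        return np.column_stack([first[:, 0], first[:, 1], first[:, 1] + 1])

    def bonded_pairs(self) -> np.ndarray:
        """(M, 2) currently bonded sticker pairs, i < j."""
        i = np.flatnonzero(self.bond_partner >= 0)
        i = i[self.bond_partner[i] > i]
        return np.column_stack([i, self.bond_partner[i]])

    # -- geometry helpers -------------------------------------------------
    def displacement(self, i, j) -> np.ndarray:
        """Minimum-image displacement r_i - r_j (vectorized over indices)."""
        return min_image(self.positions[i] - self.positions[j], self.box_length)

    def wrap(self) -> None:
        """Wrap all coordinates into [0, box)."""
        np.mod(self.positions, self.box_length, out=self.positions)

    def kinetic_temperature(self, mass: float) -> float:
        """Instantaneous kinetic temperature in K."""
        from .constants import KB_KCAL_PER_MOL_K, KCAL_PER_MOL_TO_DA_A2_FS2
        v2 = float(np.sum(self.velocities ** 2))
        ke_kcal = 0.5 * mass * v2 / KCAL_PER_MOL_TO_DA_A2_FS2
        return 2.0 * ke_kcal / (3.0 * self.n_beads * KB_KCAL_PER_MOL_K)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box_length=self.box_length,
            chain_id=self.chain_id.copy(),
            bead_index=self.bead_index.copy(),
            flavor=self.flavor.copy(),
            step=self.step,
            bond_partner=self.bond_partner.copy(),
            bond_formed_step=self.bond_formed_step.copy(),
            bond_version=self.bond_version,
        )
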