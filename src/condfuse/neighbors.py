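"""Verlet neighbor list with periodic minimum-image semantics.

Pairs are found with a periodic KD-tree at ``cutoff + skin`` and reused
until any bead has moved more than skin/2 since the last build, which
guarantees no interacting pair inside ``cutoff`` is ever missed.  For
very small systems an all-pairs list is kept instead (exact by
construction).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .state import SystemState, min_image

_BRUTE_FORCE_N = 40


class NeighborList:
    def __init__(self, cutoff: float, skin: float = 3.0):
        if skin <= 0:
            raise ValueError("skin must be positive")
        self.cutoff = cutoff
        self.skin = skin
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self.excluded = np.empty(0, dtype=bool)
        self._ref_positions: np.ndarray | None = None
        self._box = None
        self.n_builds = 0

    def _find_pairs(self, state: SystemState) -> np.ndarray:
        n = state.n_beads
        if n <= _BRUTE_FORCE_N:
            ii, jj = np.triu_indices(n, k=1)
            return np.column_stack([ii, jj])
        pos = np.mod(state.positions, state.box_length)
        tree = cKDTree(pos, boxsize=state.box_length)
        pairs = tree.query_pairs(self.cutoff + self.skin, output_type="ndarray")
        return pairs.astype(np.int64, copy=False)

    def build(self, state: SystemState, exclusion_bonds: int = 2) -> None:
        """Rebuild the pair list; precompute the intrachain exclusion mask.

        Pairs on the same chain separated by ``exclusion_bonds`` backbone
        bonds or fewer are flagged excluded from nonbonded interactions.
        """
        self.pairs = self._find_pairs(state)
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        same_chain = state.chain_id[i] == state.chain_id[j]
        close_seq = np.abs(state.bead_index[i] - state.bead_index[j]) <= exclusion_bonds
        self.excluded = same_chain & close_seq
        self._ref_positions = state.positions.copy()
        self._box = state.box_length
        self.n_builds += 1

    def needs_rebuild(self, state: SystemState) -> bool:
        if self._ref_positions is None or self._box != state.box_length:
            return True
        if len(self._ref_positions) != state.n_beads:
            return True
        if len(self._ref_positions) == 0:
            return False
        from . import _kernels

        thresh_sq = (0.5 * self.skin) ** 2
        if _kernels.HAVE_NUMBA:
            # raw displacement: a wrap jump just forces an extra rebuild
            return bool(_kernels.max_disp_exceeds(
                state.positions, self._ref_positions, thresh_sq))
        dr = min_image(state.positions - self._ref_positions, state.box_length)
        return float(np.max(np.einsum("ij,ij->i", dr, dr))) > thresh_sq

    def ensure_current(self, state: SystemState, exclusion_bonds: int = 2) -> None:
        if self.needs_rebuild(state):
            self.build(state, exclusion_bonds)
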