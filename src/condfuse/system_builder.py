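"""Construction of chains, packed boxes, compact clusters and fixtures.

The standard chain is a 35-bead two-flavor sticker-spacer polymer: five
sticker beads of one flavor at evenly spaced positions {4, 11, 18, 25,
32} (1-based) and thirty spacers, joined by harmonic springs of rest
length 10 Å.  A system mixes equal numbers of flavor-A ("red") and
flavor-B ("cyan") chains.  Builders are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .state import (FLAVOR_A, FLAVOR_B, SPACER, SystemState, min_image)

DEFAULT_STICKER_INDICES = (4, 11, 18, 25, 32)


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChainTemplate:
    """Architecture of one chain: length, sticker positions, flavor."""

    n_beads: int = 35
    sticker_indices: tuple = DEFAULT_STICKER_INDICES  # 1-based bead positions
    flavor: str = "A"
    bead_mass: float = 1000.0

    def __post_init__(self) -> None:
        idx = self.sticker_indices
        if any(i < 1 or i > self.n_beads for i in idx):
            raise ValueError("sticker indices must lie within [1, n_beads]")
        if list(idx) != sorted(set(idx)):
            raise ValueError("sticker indices must be strictly increasing")
        if self.flavor not in ("A", "B"):
            raise ValueError("flavor must be 'A' or 'B'")

    @property
    def valency(self) -> int:
        return len(self.sticker_indices)

    def flavor_codes(self) -> np.ndarray:
        codes = np.full(self.n_beads, SPACER, dtype=np.int8)
        code = FLAVOR_A if self.flavor == "A" else FLAVOR_B
        for i in self.sticker_indices:
            codes[i - 1] = code
        return codes

    def with_valency(self, valency: int) -> "ChainTemplate":
        """Evenly re-space ``valency`` stickers along the chain."""
        if valency == 0:
            return ChainTemplate(self.n_beads, (), self.flavor, self.bead_mass)
        pos = np.linspace(1, self.n_beads, valency + 2)[1:-1]
        return ChainTemplate(self.n_beads, tuple(int(round(p)) for p in pos),
                             self.flavor, self.bead_mass)


def homopolymer_template(n_beads: int = 35, flavor: str = "A") -> ChainTemplate:
    """A chain with no stickers: all interactions are nonspecific."""
    return ChainTemplate(n_beads=n_beads, sticker_indices=(), flavor=flavor)


@dataclass(frozen=True)
class SystemSpec:
    """What to build: box, chain counts per flavor, templates, seed."""

    box_length: float
    n_chains_per_flavor: int
    template_a: ChainTemplate = field(default_factory=lambda: ChainTemplate(flavor="A"))
    template_b: ChainTemplate = field(default_factory=lambda: ChainTemplate(flavor="B"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.n_chains_per_flavor < 0:
            raise ValueError("n_chains_per_flavor must be non-negative")


def build_chain(template: ChainTemplate, origin, direction,
                bond_length: float = 10.0) -> np.ndarray:
    """Collinear bead positions for one chain: (n_beads, 3) array."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    u = direction / norm
    return origin + bond_length * np.arange(template.n_beads)[:, None] * u


def _random_walk_chain(template: ChainTemplate, origin, rng,
                       bond_length: float = 10.0,
                       min_cos: float = 0.3,
                       self_avoid: float = 7.0) -> np.ndarray:
    """Compact worm-like conformation: each bond deflects within a cone
    (cos >= min_cos) and beads avoid coming closer than ``self_avoid``."""
    pos = np.empty((template.n_beads, 3))
    pos[0] = origin
    u = _random_unit(rng)
    if template.n_beads > 1:
        pos[1] = pos[0] + bond_length * u
    for k in range(2, template.n_beads):
        for _ in range(64):
            v = _random_unit(rng)
            # resample until within the allowed deflection cone
            if np.dot(v, u) < min_cos:
                continue
            cand = pos[k - 1] + bond_length * v
            d2 = np.einsum("ij,ij->i", pos[:k - 1] - cand, pos[:k - 1] - cand)
            if np.all(d2 >= self_avoid ** 2):
                break
        else:  # give up on self-avoidance, keep the cone constraint
            v = u
            cand = pos[k - 1] + bond_length * v
        pos[k] = cand
        u = v
    return pos


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _assemble(chains: list[np.ndarray], templates: list[ChainTemplate],
              box_length: float) -> SystemState:
    if chains:
        positions = np.concatenate(chains)
        flavor = np.concatenate([t.flavor_codes() for t in templates])
        chain_id = np.concatenate([np.full(len(c), k) for k, c in enumerate(chains)])
        bead_index = np.concatenate([np.arange(len(c)) for c in chains])
    else:
        positions = np.empty((0, 3))
        flavor = np.empty(0, dtype=np.int8)
        chain_id = np.empty(0, dtype=np.int64)
        bead_index = np.empty(0, dtype=np.int64)
    return SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        box_length=box_length,
        chain_id=chain_id,
        bead_index=bead_index,
        flavor=flavor,
    )


def _min_interchain_ok(new_chain: np.ndarray, placed: np.ndarray,
                       box: float, min_sep: float) -> bool:
    if len(placed) == 0:
        return True
    tree = cKDTree(np.mod(placed, box), boxsize=box)
    d, _ = tree.query(np.mod(new_chain, box), k=1)
    return bool(np.min(d) >= min_sep)


def pack_uniform(spec: SystemSpec, min_separation: float = 9.0,
                 rng: np.random.Generator | None = None,
                 conformation: str = "coil",
                 max_retries: int = 200) -> SystemState:
    """Place chains at random positions/orientations in the periodic box.

    Rejection sampling keeps every interchain bead pair at least
    ``min_separation`` apart (minimum image).  ``conformation`` is
    "coil" (compact worm-like walks) or "straight" (rods).  Raises
    :class:`PackingError` when the retry budget runs out.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    templates: list[ChainTemplate] = []
    order = ([spec.template_a] * spec.n_chains_per_flavor
             + [spec.template_b] * spec.n_chains_per_flavor)
    chains: list[np.ndarray] = []
    placed = np.empty((0, 3))
    for template in order:
        extent = (template.n_beads - 1) * 10.0
        if conformation == "straight" and extent >= spec.box_length:
            raise PackingError(
                f"straight {template.n_beads}-bead chain ({extent:.0f} Å) does "
                f"not fit in a {spec.box_length:.0f} Å box")
        for attempt in range(max_retries):
            origin = rng.uniform(0.0, spec.box_length, size=3)
            if conformation == "straight":
                chain = build_chain(template, origin, _random_unit(rng))
            elif conformation == "coil":
                chain = _random_walk_chain(template, origin, rng)
            else:
                raise ValueError(f"unknown conformation {conformation!r}")
            if _min_interchain_ok(chain, placed, spec.box_length, min_separation):
                break
        else:
            raise PackingError(
                f"could not place chain {len(chains)} after {max_retries} "
                "attempts; try a larger box or smaller min_separation")
        chains.append(chain)
        templates.append(template)
        placed = np.concatenate([placed, chain])
    return _assemble(chains, templates, spec.box_length)


def pack_compact_cluster(n_chains_per_flavor: int,
                         box_length: float,
                         cluster_radius: float,
                         template_a: ChainTemplate | None = None,
                         template_b: ChainTemplate | None = None,
                         min_separation: float = 7.0,
                         seed: int | np.random.Generator = 0,
                         max_retries: int = 400) -> SystemState:
    """Pack chains as coils with start points inside a sphere at the box
    center — a pre-collapsed single cluster for relax/fusion protocols."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template_a = template_a or ChainTemplate(flavor="A")
    template_b = template_b or ChainTemplate(flavor="B")
    center = np.full(3, box_length / 2.0)
    order = ([template_a] * n_chains_per_flavor + [template_b] * n_chains_per_flavor)
    # interleave flavors so the cluster is well mixed from the start
    order = [order[i // 2 + (len(order) // 2) * (i % 2)] for i in range(len(order))]
    chains: list[np.ndarray] = []
    placed = np.empty((0, 3))
    for template in order:
        for attempt in range(max_retries):
            u = _random_unit(rng) * cluster_radius * rng.random() ** (1 / 3)
            chain = _random_walk_chain(template, center + u, rng)
            if _min_interchain_ok(chain, placed, box_length, min_separation):
                break
        else:
            raise PackingError("could not pack compact cluster; "
                               "increase cluster_radius")
        chains.append(chain)
        placed = np.concatenate([placed, chain])
    return _assemble(chains, order, box_length)


# ---------------------------------------------------------------------------
# cluster duplication for fusion runs


def radius_of_gyration(positions: np.ndarray, box_length: float | None = None) -> float:
    """All-bead Rg about the center of geometry (minimum-image unwrapped
    relative to the first bead when a box is given)."""
    pos = np.asarray(positions, dtype=float)
    if box_length is not None:
        pos = pos[0] + min_image(pos - pos[0], box_length)
    d = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def duplicate_cluster(state: SystemState, axis=(1.0, 0.0, 0.0),
                      box_margin: float = 2.0):
    """Copy a relaxed single cluster to set up a two-cluster fusion run.

    The copy is displaced along ``axis`` (+x by default) so the two
    center-of-geometry separations equal 3 Rg_cluster, where Rg_cluster
    is the all-bead radius of gyration of the input.  The box is enlarged
    when needed so the images do not interact across the boundary.
    Returns ``(two_cluster_state, chain_labels, rg_cluster)``; labels are
    1 for the original chains and 2 for the copy, and the bond registry
    of the copy is an index-shifted image of the original's.
    """
    n = state.n_beads
    if n == 0:
        raise ValueError("cannot duplicate an empty state")
    pos = state.positions
    pos = pos[0] + min_image(pos - pos[0], state.box_length)
    rg = radius_of_gyration(pos)
    separation = 3.0 * rg
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    shift = separation * u

    extent = pos.max(axis=0) - pos.min(axis=0)
    needed = float(np.max(extent) + separation) * box_margin
    box = max(state.box_length, needed)
    if separation > box / 2.0:
        raise ValueError("cluster separation exceeds half the enlarged box")

    cog = pos.mean(axis=0)
    centered = pos - cog + box / 2.0
    new_pos = np.concatenate([centered - shift / 2.0, centered + shift / 2.0])

    partner = state.bond_partner
    new_partner = np.concatenate([
        np.where(partner >= 0, partner, -1),
        np.where(partner >= 0, partner + n, -1),
    ])
    new_state = SystemState(
        positions=new_pos,
        velocities=np.concatenate([state.velocities, state.velocities]),
        box_length=box,
        chain_id=np.concatenate([state.chain_id, state.chain_id + state.n_chains]),
        bead_index=np.concatenate([state.bead_index, state.bead_index]),
        flavor=np.concatenate([state.flavor, state.flavor]),
        step=state.step,
        bond_partner=new_partner,
        bond_formed_step=np.concatenate([state.bond_formed_step,
                                         state.bond_formed_step]),
    )
    new_state.wrap()
    labels = np.concatenate([np.ones(state.n_chains, dtype=np.int64),
                             np.full(state.n_chains, 2, dtype=np.int64)])
    return new_state, labels, rg


# ---------------------------------------------------------------------------
# deterministic test fixtures


def dimer_array(n_dimers: int, spacing: float = 50.0) -> SystemState:
    """Grid of pre-bonded single-bead sticker dimers (A-B), one per cell.

    Dimers are far enough apart to evolve essentially independently,
    which multiplies bond-kinetics statistics (lifetimes, dissociation
    counts) per simulated step.
    """
    if n_dimers < 1:
        raise ValueError("need at least one dimer")
    per_side = int(np.ceil(n_dimers ** (1 / 3)))
    box = per_side * spacing
    positions, flavors = [], []
    k = 0
    for ix in range(per_side):
        for iy in range(per_side):
            for iz in range(per_side):
                if k >= n_dimers:
                    break
                base = (np.array([ix, iy, iz]) + 0.5) * spacing
                positions.append(base - [11.22 / 2, 0, 0])
                positions.append(base + [11.22 / 2, 0, 0])
                flavors.extend([FLAVOR_A, FLAVOR_B])
                k += 1
    n = 2 * n_dimers
    state = SystemState(
        positions=np.array(positions),
        velocities=np.zeros((n, 3)),
        box_length=box,
        chain_id=np.arange(n),
        bead_index=np.zeros(n, dtype=np.int64),
        flavor=np.array(flavors, dtype=np.int8),
    )
    ids = np.arange(0, n, 2)
    state.bond_partner[ids] = ids + 1
    state.bond_partner[ids + 1] = ids
    return state


def make_fixture(name: str) -> SystemState:
    """Small deterministic systems with documented geometry.

    * ``dimer`` — two single-bead chains, complementary stickers at the
      bond rest distance, pre-bonded, in a 60 Å box.
    * ``two-chain`` — one A and one B chain coiled near each other.
    * ``microcluster-10`` — ten chains (5 + 5) packed into a compact
      cluster, fixed seed.
    * ``homodroplet`` — ten sticker-free chains packed compactly (purely
      nonspecific interactions).
    """
    if name == "dimer":
        positions = np.array([[24.0, 30.0, 30.0], [24.0 + 11.22, 30.0, 30.0]])
        state = SystemState(
            positions=positions,
            velocities=np.zeros((2, 3)),
            box_length=60.0,
            chain_id=np.array([0, 1]),
            bead_index=np.array([0, 0]),
            flavor=np.array([FLAVOR_A, FLAVOR_B], dtype=np.int8),
        )
        state.bond_partner[:] = [1, 0]
        return state
    if name == "two-chain":
        rng = np.random.default_rng(7)
        a = _random_walk_chain(ChainTemplate(flavor="A"), (80.0, 100.0, 100.0), rng)
        b = _random_walk_chain(ChainTemplate(flavor="B"), (120.0, 100.0, 100.0), rng)
        return _assemble([a, b], [ChainTemplate(flavor="A"),
                                  ChainTemplate(flavor="B")], 200.0)
    if name == "microcluster-10":
        return pack_compact_cluster(5, box_length=300.0, cluster_radius=30.0,
                                    seed=42)
    if name == "homodroplet":
        t = homopolymer_template()
        return pack_compact_cluster(5, box_length=300.0, cluster_radius=30.0,
                                    template_a=t, template_b=t, seed=43)
    raise KeyError(f"unknown fixture {name!r}")
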