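"""Observables for condensate coalescence and kinetic arrest.

Conventions:

* ``labels`` maps each chain (0-based id) to its cluster of origin,
  1 or 2, assigned once when a fusion run is set up; labels are
  provenance and never change during the run.
* Bonds and contacts are classified as 11 (both chains from cluster 1),
  22, or 12 (one from each).
* The relative intercluster distance is R_dist = R_clusters/σ_cluster,
  where σ_cluster (the cluster "diameter") is 2 Rg of the relaxed
  single cluster, measured once and then held fixed; R_dist ≈ 1 at
  surface contact and 0 for a completely fused pair.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .state import SystemState, min_image
from .system_builder import radius_of_gyration

CONTACT_CUTOFF = 22.44  # Å

__all__ = [
    "CONTACT_CUTOFF", "relative_distance", "cluster_distance",
    "sigma_cluster_from_rg", "cluster_density", "sticker_occupancy",
    "dissociation_rate", "classify_bonds", "bond_exchange_entropy",
    "contact_count", "hull_surface_volume", "bond_network",
    "degree_distribution", "largest_component_fraction",
    "extent_of_fusion", "radial_occupancy_profile",
]


# ---------------------------------------------------------------------------
# cluster geometry


def _group_centroid(state: SystemState, bead_ids: np.ndarray) -> np.ndarray:
    pos = state.positions[bead_ids]
    ref = pos[0]
    return ref + min_image(pos - ref, state.box_length).mean(axis=0)


def cluster_distance(state: SystemState, labels: np.ndarray) -> float:
    """Minimum-image distance between the chain-center centroids of the
    two labeled groups."""
    labels = np.asarray(labels)
    centers = state.chain_center_ids()
    g1 = centers[labels == 1]
    g2 = centers[labels == 2]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both label groups must be non-empty")
    c1 = _group_centroid(state, g1)
    c2 = _group_centroid(state, g2)
    return float(np.linalg.norm(min_image(c1 - c2, state.box_length)))


def sigma_cluster_from_rg(rg: float, convention: str = "2rg") -> float:
    """Cluster diameter from its radius of gyration.

    ``2rg`` (default) takes the diameter as twice Rg; ``hard-sphere``
    uses the radius of the uniform ball with that Rg, 2·sqrt(5/3)·Rg.
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    if convention == "2rg":
        return 2.0 * rg
    if convention == "hard-sphere":
        return 2.0 * np.sqrt(5.0 / 3.0) * rg
    raise ValueError(f"unknown sigma_cluster convention {convention!r}")


def relative_distance(state: SystemState, labels: np.ndarray,
                      sigma_cluster: float) -> float:
    """R_dist = R_clusters / σ_cluster (dimensionless)."""
    if sigma_cluster <= 0:
        raise ValueError("sigma_cluster must be positive")
    return cluster_distance(state, labels) / sigma_cluster


def extent_of_fusion(r_dist_final: float) -> float:
    """1 - R_dist(t_f); negative values (clusters beyond one diameter)
    are reported raw."""
    return 1.0 - r_dist_final


def cluster_density(positions: np.ndarray, box_length: float | None = None) -> float:
    """Bead number density N / ((4/3) π Rg³) in beads/Å³, with Rg over
    all member beads.  Returns inf (flagged) for degenerate geometry."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("density needs at least two beads")
    rg = radius_of_gyration(positions, box_length)
    if rg <= 0:
        return float("inf")
    return len(positions) / (4.0 / 3.0 * np.pi * rg ** 3)


# ---------------------------------------------------------------------------
# bonds


def sticker_occupancy(state: SystemState) -> float:
    """Fraction of the sticker population currently bonded."""
    stickers = state.sticker_mask
    n = int(np.count_nonzero(stickers))
    if n == 0:
        raise ValueError("system has no stickers")
    return float(np.count_nonzero(state.bond_partner[stickers] >= 0) / n)


def dissociation_rate(break_steps: np.ndarray, window: int,
                      n_steps: int | None = None,
                      n_stickers: int | None = None) -> np.ndarray:
    """Break events bucketed by observation window.

    ``break_steps`` are the step stamps of break events (see
    :class:`condfuse.bond_kinetics.EventLog`).  Counts are per window of
    ``window`` steps covering [0, n_steps); pass ``n_stickers`` to
    normalize to events per sticker.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    break_steps = np.asarray(break_steps, dtype=np.int64)
    last = n_steps if n_steps is not None else (
        int(break_steps.max()) + 1 if len(break_steps) else window)
    n_windows = max(1, int(np.ceil(last / window)))
    counts = np.bincount(break_steps // window, minlength=n_windows).astype(float)
    counts = counts[:n_windows]
    if n_stickers:
        counts = counts / n_stickers
    return counts


def classify_bonds(bond_pairs: np.ndarray, chain_id: np.ndarray,
                   labels: np.ndarray) -> dict:
    """Counts of 11/22/12 bonds given bead-pair list and chain labels."""
    labels = np.asarray(labels)
    if len(bond_pairs) == 0:
        return {"total": 0, "11": 0, "22": 0, "12": 0}
    li = labels[chain_id[bond_pairs[:, 0]]]
    lj = labels[chain_id[bond_pairs[:, 1]]]
    c11 = int(np.count_nonzero((li == 1) & (lj == 1)))
    c22 = int(np.count_nonzero((li == 2) & (lj == 2)))
    c12 = int(np.count_nonzero(li != lj))
    return {"total": len(bond_pairs), "11": c11, "22": c22, "12": c12}


def bond_exchange_entropy(bond_pairs: np.ndarray, chain_id: np.ndarray,
                          labels: np.ndarray) -> float:
    """Shannon entropy (nats) of the bond distribution over the three
    classes 11/22/12; ln 3 ≈ 1.1 for a fully mixed two-cluster system.

    Returns NaN (flagged undefined) when there are no bonds.
    """
    counts = classify_bonds(bond_pairs, chain_id, labels)
    total = counts["total"]
    if total == 0:
        return float("nan")
    p = np.array([counts["11"], counts["22"], counts["12"]], dtype=float) / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


# ---------------------------------------------------------------------------
# contacts


def contact_pairs(state: SystemState, cutoff: float = CONTACT_CUTOFF,
                  exclusion_bonds: int = 2) -> np.ndarray:
    """Unordered bead pairs within ``cutoff`` (minimum image), skipping
    intrachain pairs within ``exclusion_bonds`` backbone bonds."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.mod(state.positions, state.box_length)
    tree = cKDTree(pos, boxsize=state.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    excluded = ((state.chain_id[i] == state.chain_id[j])
                & (np.abs(state.bead_index[i] - state.bead_index[j])
                   <= exclusion_bonds))
    return pairs[~excluded]


def contact_count(state: SystemState, labels: np.ndarray | None = None,
                  cutoff: float = CONTACT_CUTOFF) -> dict:
    """Contact counts (total and 11/22/12 when labels are given)."""
    pairs = contact_pairs(state, cutoff)
    if labels is None:
        return {"total": len(pairs)}
    return classify_bonds(pairs, state.chain_id, np.asarray(labels))


# ---------------------------------------------------------------------------
# convex hull


def hull_surface_volume(positions: np.ndarray) -> tuple[float, float, float]:
    """Convex-hull surface area (Å²), volume (Å³) and their ratio (Å⁻¹).

    Returns flagged NaNs for degenerate (coplanar or < 4 point) input.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 4:
        return float("nan"), float("nan"), float("nan")
    try:
        hull = ConvexHull(positions)
    except Exception:
        return float("nan"), float("nan"), float("nan")
    surface, volume = float(hull.area), float(hull.volume)
    return surface, volume, surface / volume


# ---------------------------------------------------------------------------
# chain-level bonded network


def bond_network(state: SystemState):
    """Chain-level graph: nodes are chains, edges intersticker bonds.

    Multi-edges are collapsed; edge attribute ``multiplicity`` counts the
    bonds joining the two chains.  Intrachain bonds appear as self-loops.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(state.n_chains))
    for i, j in state.bonded_pairs():
        ci, cj = int(state.chain_id[i]), int(state.chain_id[j])
        if g.has_edge(ci, cj):
            g[ci][cj]["multiplicity"] += 1
        else:
            g.add_edge(ci, cj, multiplicity=1)
    return g


def degree_distribution(graph) -> np.ndarray:
    """Histogram of node degrees, index = degree."""
    degrees = [d for _, d in graph.degree()]
    return np.bincount(degrees) if degrees else np.zeros(1, dtype=np.int64)


def largest_component_fraction(graph) -> float:
    """Fraction of chains in the largest connected component — the
    cluster-stability criterion (≥ 0.9 counts as a stable cluster)."""
    import networkx as nx

    n = graph.number_of_nodes()
    if n == 0:
        return float("nan")
    return max(len(c) for c in nx.connected_components(graph)) / n


def contact_network(state: SystemState, cutoff: float = CONTACT_CUTOFF):
    """Chain-level graph with edges between chains sharing >= 1 contact;
    the connectivity notion used for homopolymer (sticker-free) systems."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(state.n_chains))
    pairs = contact_pairs(state, cutoff)
    if len(pairs):
        ci = state.chain_id[pairs[:, 0]]
        cj = state.chain_id[pairs[:, 1]]
        inter = ci != cj
        for a, b in zip(ci[inter], cj[inter]):
            g.add_edge(int(a), int(b))
    return g


# ---------------------------------------------------------------------------
# radial profile


def radial_occupancy_profile(state: SystemState, n_shells: int = 4) -> np.ndarray:
    """Sticker occupancy in equal-count radial shells about the cluster
    centroid (all beads), innermost shell first."""
    if n_shells < 2:
        raise ValueError("need at least two shells")
    sticker_ids = np.flatnonzero(state.sticker_mask)
    if len(sticker_ids) < n_shells:
        raise ValueError("fewer stickers than shells")
    pos = state.positions
    pos = pos[0] + min_image(pos - pos[0], state.box_length)
    centroid = pos.mean(axis=0)
    r = np.linalg.norm(pos[sticker_ids] - centroid, axis=1)
    order = np.argsort(r)
    bonded = state.bond_partner[sticker_ids] >= 0
    shells = np.array_split(order, n_shells)
    return np.array([float(np.mean(bonded[s])) for s in shells])
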