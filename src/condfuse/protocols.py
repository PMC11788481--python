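"""Canned simulation protocols: collapse, relax, fuse, phase scan.

The full workflow mirrors the three-stage coalescence study design:

1. **collapse** — bias a dilute solution along the system radius of
   gyration (chain-center beads) until it condenses into one cluster;
   run at Es = 10 kT, Ens = 0.5 kT.
2. **relax** — unbiased Langevin dynamics of the single cluster at the
   (Es, Ens) pair under study.
3. **fuse** — duplicate the relaxed cluster at a center separation of
   3 Rg_cluster and bias the intercluster center distance with
   well-tempered metadynamics; record R_dist(t) with σ_cluster = 2 Rg
   frozen at duplication time.

``phase_scan`` repeats relax + fuse over a grid of (Es, Ens) and
tabulates the extent of fusion, 1 - R_dist(t_f).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .dynamics import RunResult, run, thermalize_velocities
from .metadynamics import (ClusterDistanceCV, MetadynamicsBias, RgSystemCV,
                           WellTemperedParams)
from .model_core import ForceField, ThermoParams
from .state import SystemState
from .system_builder import (ChainTemplate, duplicate_cluster,
                             pack_compact_cluster)

COLLAPSE_ES_KT = 10.0
COLLAPSE_ENS_KT = 0.5


class PairRestraintBias:
    """Harmonic restraints between chosen bead pairs (builder tool).

    V = k/2 (R - r0)² per pair.  Used by the cluster annealer to steer
    matched free stickers into bonding range; never part of production
    force fields.
    """

    def __init__(self, k: float, r0: float):
        self.k = k
        self.r0 = r0
        self.pairs = np.empty((0, 2), dtype=np.int64)

    def bead_forces(self, state: SystemState):
        F = np.zeros_like(state.positions)
        if len(self.pairs) == 0:
            return F, 0.0
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        dr = state.displacement(i, j)
        r = np.linalg.norm(dr, axis=1)
        ds = r - self.r0
        fvec = (-self.k * ds / np.maximum(r, 1e-12))[:, None] * dr
        np.add.at(F, i, fvec)
        np.add.at(F, j, -fvec)
        return F, float(0.5 * self.k * np.sum(ds ** 2))

    def cv_value(self, state: SystemState) -> float:
        return float("nan")

    def due(self, step: int) -> bool:
        return False


def _match_free_stickers(state: SystemState, capture_radius: float) -> np.ndarray:
    """Greedy nearest-first matching of free complementary stickers.

    Matching favors chain pairs that do not already share a bond (caps
    rise 1 -> 2 -> unbounded over successive passes), so the resulting
    network percolates across chains instead of saturating into isolated
    fully-paired chain couples.
    """
    free = np.flatnonzero(state.sticker_mask & (state.bond_partner < 0))
    fa = free[state.flavor[free] == 1]
    fb = free[state.flavor[free] == 2]
    if len(fa) == 0 or len(fb) == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(
        state.positions[fa][:, None] - state.positions[fb][None, :], axis=-1)
    flat_order = np.argsort(d, axis=None)
    candidates = []
    for flat in flat_order:
        ai, bi = np.unravel_index(flat, d.shape)
        if d[ai, bi] > capture_radius:
            break
        candidates.append((int(fa[ai]), int(fb[bi])))

    pair_count: dict = {}
    for i, j in state.bonded_pairs():
        key = tuple(sorted((int(state.chain_id[i]), int(state.chain_id[j]))))
        pair_count[key] = pair_count.get(key, 0) + 1

    taken_a, taken_b, out = set(), set(), []
    for cap in (1, 2, 10 ** 9):
        for i, j in candidates:
            if i in taken_a or j in taken_b:
                continue
            key = tuple(sorted((int(state.chain_id[i]),
                                int(state.chain_id[j]))))
            if pair_count.get(key, 0) >= cap:
                continue
            taken_a.add(i)
            taken_b.add(j)
            pair_count[key] = pair_count.get(key, 0) + 1
            out.append((i, j))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def anneal_bonded_cluster(state: SystemState, ff: ForceField,
                          thermo: ThermoParams | None = None,
                          seed: int = 0,
                          target_occupancy: float = 0.9,
                          capture_radius: float = 60.0,
                          k_restraint: float = 0.15,
                          match_every: int = 4000,
                          max_steps: int = 80_000) -> SystemState:
    """Anneal a packed cluster into a bonded, near-saturated network.

    Free complementary stickers are greedily matched (nearest first) and
    pulled together by temporary harmonic restraints while the normal
    bond kinetics run; once a matched pair enters the capture cutoff it
    bonds through the standard rules and its restraint is dropped.  Stops
    at ``target_occupancy`` or after ``max_steps``.  This stands in for
    the production-scale relaxation (hundreds of millions of steps) that
    saturates sticker pairing by diffusion alone.
    """
    thermo = thermo or ThermoParams()
    rng = np.random.default_rng(seed)
    thermalize_velocities(state, thermo, rng)
    restraint = PairRestraintBias(k=k_restraint, r0=ff.R0_bond)
    n_stickers = int(np.count_nonzero(state.sticker_mask))
    if n_stickers == 0:
        raise ValueError("cluster has no stickers to anneal")
    # weak Rg confinement keeps the cluster at condensate density while
    # the restraints reorganize the network
    from .metadynamics import CompositeBias, HarmonicWallBias, RgSystemCV

    rho_target = 1.5e-3  # beads/Å^3, typical condensate density
    rg_target = (3.0 * state.n_beads / (4.0 * np.pi * rho_target)) ** (1 / 3)
    wall = HarmonicWallBias(RgSystemCV(np.arange(state.n_beads)), k=3.0,
                            upper=rg_target)
    bias = CompositeBias(restraint, wall)
    for _ in range(max_steps // match_every):
        occ = np.count_nonzero(state.bond_partner[state.sticker_mask] >= 0) / n_stickers
        if occ >= target_occupancy:
            break
        restraint.pairs = _match_free_stickers(state, capture_radius)
        run(state, ff, match_every, thermo=thermo, seed=rng,
            bias=bias, force_cap=50.0)
    return state


@dataclass
class FusionResult:
    """Outcome of a two-cluster fusion run."""

    result: RunResult
    labels: np.ndarray
    rg_cluster: float
    sigma_cluster: float
    r_dist: pd.DataFrame          # step, r_dist, and bond/entropy columns
    extent_of_fusion: float


def collapse(state: SystemState, n_steps: int,
             thermo: ThermoParams | None = None,
             meta: WellTemperedParams | None = None,
             seed: int = 0, **run_kwargs) -> RunResult:
    """Stage 1: metadynamics along Rg_system toward the clustered state."""
    ff = ForceField.from_kt(COLLAPSE_ES_KT, COLLAPSE_ENS_KT)
    meta = meta or WellTemperedParams(w0=0.3, sigma_G=2.0, pace=500, gamma=10.0)
    bias = MetadynamicsBias(RgSystemCV(state.chain_center_ids()), meta)
    rng = np.random.default_rng(seed)
    thermalize_velocities(state, thermo or ThermoParams(), rng)
    return run(state, ff, n_steps, thermo=thermo, seed=rng, bias=bias,
               **run_kwargs)


def relax(state: SystemState, ff: ForceField, n_steps: int,
          thermo: ThermoParams | None = None, seed: int = 0,
          **run_kwargs) -> RunResult:
    """Stage 2: unbiased Langevin relaxation of a single cluster."""
    rng = np.random.default_rng(seed)
    thermalize_velocities(state, thermo or ThermoParams(), rng)
    return run(state, ff, n_steps, thermo=thermo, seed=rng, **run_kwargs)


def fuse(relaxed: SystemState, ff: ForceField, n_steps: int,
         thermo: ThermoParams | None = None,
         meta: WellTemperedParams | None = None,
         seed: int = 0,
         metrics_every: int = 500,
         snapshot_every: int | None = None,
         approach_frac: float = 0.35,
         steer_k: float = 0.5,
         wall_k: float = 2.0,
         **run_kwargs) -> FusionResult:
    """Stage 3: duplicate the relaxed cluster and bias the fusion CV.

    The run has two phases.  First a moving harmonic restraint steers the
    intercluster distance from the initial 3 Rg separation down to one
    cluster diameter (surface contact) over ``approach_frac`` of the
    steps — at desk scale plain hill deposition cannot drag free clusters
    over tens of Å in reasonable time.  Then well-tempered metadynamics
    on the same CV, confined by an upper wall just outside contact,
    drives the exploration of interpenetration; whether the centers can
    actually approach is decided by the cluster's ability to exchange
    stickers, not by the bias.  σ_cluster is measured (as 2 Rg of the
    relaxed cluster) before duplication and held fixed for the whole
    R_dist(t) series.
    """
    from .metadynamics import CompositeBias, HarmonicWallBias, SteeringBias

    state, labels, rg = duplicate_cluster(relaxed)
    sigma_cluster = analysis.sigma_cluster_from_rg(rg)
    centers = state.chain_center_ids()
    cv = ClusterDistanceCV(centers[labels == 1], centers[labels == 2])
    meta = meta or WellTemperedParams(w0=1.5, sigma_G=8.0, pace=250, gamma=8.0)
    rng = np.random.default_rng(seed)
    thermalize_velocities(state, thermo or ThermoParams(), rng)

    approach_steps = max(1, int(n_steps * approach_frac))
    start_step = state.step
    steer = SteeringBias(cv, k=steer_k, s_from=cv.value(state),
                         s_to=sigma_cluster, t_start=start_step,
                         t_end=start_step + approach_steps)
    res1 = run(state, ff, approach_steps, thermo=thermo, seed=rng, bias=steer,
               metrics_every=metrics_every, snapshot_every=snapshot_every,
               **run_kwargs)
    bias2 = CompositeBias(
        MetadynamicsBias(cv, meta),
        HarmonicWallBias(cv, k=wall_k, upper=1.1 * sigma_cluster),
    )
    result = run(state, ff, n_steps - approach_steps, thermo=thermo, seed=rng,
                 bias=bias2, metrics_every=metrics_every,
                 snapshot_every=snapshot_every, event_log=res1.event_log,
                 **run_kwargs)
    result.frames = res1.frames + result.frames
    result.metrics = pd.concat([res1.metrics, result.metrics],
                               ignore_index=True)

    rows = []
    frames = result.frames or []
    for frame in frames:
        snap = state.copy()
        snap.positions = frame.positions
        counts = analysis.classify_bonds(frame.bonds, state.chain_id, labels)
        rows.append({
            "step": frame.step,
            "r_dist": analysis.cluster_distance(snap, labels) / sigma_cluster,
            "n_bonds": counts["total"], "c11": counts["11"],
            "c22": counts["22"], "c12": counts["12"],
            "entropy": analysis.bond_exchange_entropy(
                frame.bonds, state.chain_id, labels),
        })
    if not rows:  # fall back to the final state only
        counts = analysis.classify_bonds(state.bonded_pairs(),
                                         state.chain_id, labels)
        rows.append({
            "step": state.step,
            "r_dist": analysis.cluster_distance(state, labels) / sigma_cluster,
            "n_bonds": counts["total"], "c11": counts["11"],
            "c22": counts["22"], "c12": counts["12"],
            "entropy": analysis.bond_exchange_entropy(
                state.bonded_pairs(), state.chain_id, labels),
        })
    r_dist = pd.DataFrame(rows)
    final = float(r_dist["r_dist"].iloc[-1])
    return FusionResult(result=result, labels=labels, rg_cluster=rg,
                        sigma_cluster=sigma_cluster, r_dist=r_dist,
                        extent_of_fusion=analysis.extent_of_fusion(final))


def fusion_pipeline(es_kt: float, ens_kt: float,
                    n_chains_per_flavor: int = 4,
                    relax_steps: int = 10_000,
                    fuse_steps: int = 60_000,
                    seed: int = 0,
                    template_a: ChainTemplate | None = None,
                    template_b: ChainTemplate | None = None,
                    cluster_radius: float = 30.0,
                    box_length: float = 400.0,
                    meta: WellTemperedParams | None = None,
                    snapshot_every: int = 2000,
                    thermo: ThermoParams | None = None,
                    anneal_target: float = 0.9,
                    anneal_max_steps: int = 80_000) -> FusionResult:
    """Relax a compact cluster at (Es, Ens), duplicate it and run fusion.

    Energies are quoted in kT.  The initial cluster is packed directly in
    a compact conformation and annealed into a bonded network (stage-1
    collapse plus production-length relaxation produce an equivalent
    starting point at far greater cost); sticker-free (homopolymer)
    systems skip annealing since their cohesion is purely nonspecific.
    """
    ff = ForceField.from_kt(es_kt, ens_kt)
    state = pack_compact_cluster(n_chains_per_flavor, box_length=box_length,
                                 cluster_radius=cluster_radius,
                                 template_a=template_a, template_b=template_b,
                                 seed=seed)
    # overlap removal: capped forces, no bond moves yet
    run(state, ff, 500, thermo=thermo, seed=seed, bond_updates=False,
        force_cap=20.0)
    if state.sticker_mask.any() and ff.Es > 0:
        anneal_bonded_cluster(state, ff, thermo=thermo, seed=seed + 3,
                              target_occupancy=anneal_target,
                              max_steps=anneal_max_steps)
    relax(state, ff, relax_steps, thermo=thermo, seed=seed + 1)
    return fuse(state, ff, fuse_steps, thermo=thermo, meta=meta,
                seed=seed + 2, snapshot_every=snapshot_every)


def phase_scan(es_grid_kt, ens_grid_kt, seeds=(0,),
               **pipeline_kwargs) -> pd.DataFrame:
    """Extent-of-fusion table over an (Es, Ens) grid (energies in kT).

    Each grid point is averaged over ``seeds``; returns one row per
    (Es, Ens) with mean extent of fusion and final R_dist.
    """
    rows = []
    for es in es_grid_kt:
        for ens in ens_grid_kt:
            extents, finals = [], []
            for seed in seeds:
                out = fusion_pipeline(es, ens, seed=seed, **pipeline_kwargs)
                extents.append(out.extent_of_fusion)
                finals.append(float(out.r_dist["r_dist"].iloc[-1]))
            rows.append({"Es_kT": es, "Ens_kT": ens,
                         "extent_of_fusion": float(np.mean(extents)),
                         "r_dist_final": float(np.mean(finals)),
                         "n_trials": len(seeds)})
    return pd.DataFrame(rows)
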