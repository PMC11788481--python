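"""Observable suite: R_dist, density, occupancy, entropy, contacts,
hulls, networks, radial profiles."""

import numpy as np
import pytest

from condfuse import SystemState, analysis
from condfuse.state import FLAVOR_A, FLAVOR_B


def labeled_two_cluster(offset, n_per_cluster=4, box=400.0, bead_per_chain=1):
    """Two point groups of single-bead chains with origin labels 1/2."""
    rng = np.random.default_rng(0)
    c1 = rng.normal(scale=5.0, size=(n_per_cluster, 3)) + 100.0
    c2 = rng.normal(scale=5.0, size=(n_per_cluster, 3)) + 100.0 + np.asarray(offset)
    pts = np.vstack([c1, c2])
    n = len(pts)
    st = SystemState(
        positions=pts,
        velocities=np.zeros((n, 3)),
        box_length=box,
        chain_id=np.arange(n),
        bead_index=np.zeros(n, dtype=int),
        flavor=np.tile([FLAVOR_A, FLAVOR_B], n // 2).astype(np.int8),
    )
    labels = np.repeat([1, 2], n_per_cluster)
    return st, labels


class TestRelativeDistance:
    def test_coincident_centroids_give_zero(self):
        st, labels = labeled_two_cluster([0.0, 0.0, 0.0])
        # force exact coincidence of the two groups
        st.positions[4:] = st.positions[:4]
        assert analysis.relative_distance(st, labels, sigma_cluster=50.0) == 0.0

    def test_contact_at_one_cluster_diameter(self):
        st, labels = labeled_two_cluster([0, 0, 0])
        st.positions[4:] = st.positions[:4] + [80.0, 0, 0]
        assert analysis.relative_distance(st, labels, 80.0) == pytest.approx(1.0)

    def test_ratio_of_separation_to_diameter(self):
        st, labels = labeled_two_cluster([0, 0, 0])
        rg = 40.0
        st.positions[4:] = st.positions[:4] + [3 * rg, 0, 0]
        assert analysis.relative_distance(st, labels, 2 * rg) == pytest.approx(1.5)

    def test_empty_label_group_rejected(self):
        st, labels = labeled_two_cluster([10, 0, 0])
        with pytest.raises(ValueError):
            analysis.relative_distance(st, np.ones_like(labels), 50.0)

    def test_extent_of_fusion_convention(self):
        assert analysis.extent_of_fusion(0.0) == 1.0
        assert analysis.extent_of_fusion(1.0) == 0.0
        assert analysis.extent_of_fusion(1.2) == pytest.approx(-0.2)


class TestDensity:
    def test_direct_formula(self):
        # N / ((4/3) pi Rg^3) for a synthetic cloud scaled to Rg = 50
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(1000, 3))
        pts -= pts.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum(pts ** 2, axis=1)))
        pts *= 50.0 / rg
        got = analysis.cluster_density(pts)
        assert got == pytest.approx(1000 / (4 / 3 * np.pi * 50.0 ** 3), rel=1e-9)
        assert got == pytest.approx(1.91e-3, rel=0.01)

    def test_dilation_scales_inverse_cube(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=20.0, size=(500, 3))
        centroid = pts.mean(axis=0)
        doubled = centroid + 2.0 * (pts - centroid)
        assert analysis.cluster_density(doubled) == pytest.approx(
            analysis.cluster_density(pts) / 8.0, rel=1e-9)

    def test_needs_two_beads(self):
        with pytest.raises(ValueError):
            analysis.cluster_density(np.zeros((1, 3)))

    def test_degenerate_geometry_flagged_infinite(self):
        assert np.isinf(analysis.cluster_density(np.zeros((5, 3))))


class TestOccupancy:
    def test_fraction_bonded(self, dimer):
        assert analysis.sticker_occupancy(dimer) == 1.0
        dimer.bond_partner[:] = -1
        assert analysis.sticker_occupancy(dimer) == 0.0

    def test_half_bonded(self):
        st, _ = labeled_two_cluster([30, 0, 0])
        st.bond_partner[0], st.bond_partner[1] = 1, 0
        st.bond_partner[2], st.bond_partner[3] = 3, 2
        assert analysis.sticker_occupancy(st) == pytest.approx(4 / 8)

    def test_no_stickers_rejected(self):
        st, _ = labeled_two_cluster([30, 0, 0])
        st.flavor[:] = 0
        with pytest.raises(ValueError):
            analysis.sticker_occupancy(st)


class TestDissociationRate:
    def test_window_bucketing(self):
        counts = analysis.dissociation_rate(np.array([5, 15, 25]), window=20,
                                            n_steps=40)
        np.testing.assert_array_equal(counts, [2, 1])

    def test_empty_log_gives_zeros(self):
        counts = analysis.dissociation_rate(np.array([], dtype=int), window=10,
                                            n_steps=50)
        np.testing.assert_array_equal(counts, np.zeros(5))

    def test_per_sticker_normalization(self):
        counts = analysis.dissociation_rate(np.array([1, 2, 3]), window=10,
                                            n_steps=10, n_stickers=6)
        np.testing.assert_allclose(counts, [0.5])


class TestBondExchangeEntropy:
    def test_uniform_three_state_maximum(self):
        # p = (1/3, 1/3, 1/3) -> ln 3, the fully mixed two-cluster state
        st, labels = labeled_two_cluster([20, 0, 0], n_per_cluster=4)
        pairs = np.array([[0, 1], [4, 5], [2, 6]])  # 11, 22, 12
        h = analysis.bond_exchange_entropy(pairs, st.chain_id, labels)
        assert h == pytest.approx(np.log(3.0), rel=1e-12)
        assert h == pytest.approx(1.1, abs=0.01)

    def test_single_class_gives_zero(self):
        st, labels = labeled_two_cluster([20, 0, 0])
        pairs = np.array([[0, 1], [1, 2], [2, 3]])  # all intracluster-1
        assert analysis.bond_exchange_entropy(pairs, st.chain_id, labels) == 0.0

    def test_two_equal_classes_give_ln2(self):
        st, labels = labeled_two_cluster([20, 0, 0])
        pairs = np.array([[0, 1], [4, 5]])  # one 11, one 22
        assert analysis.bond_exchange_entropy(
            pairs, st.chain_id, labels) == pytest.approx(np.log(2.0))

    def test_no_bonds_flagged_nan(self):
        st, labels = labeled_two_cluster([20, 0, 0])
        assert np.isnan(analysis.bond_exchange_entropy(
            np.empty((0, 2), dtype=int), st.chain_id, labels))

    def test_decomposition_sums_to_total(self):
        st, labels = labeled_two_cluster([20, 0, 0], n_per_cluster=6)
        rng = np.random.default_rng(3)
        pairs = rng.integers(0, 12, size=(30, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        counts = analysis.classify_bonds(pairs, st.chain_id, labels)
        assert counts["11"] + counts["22"] + counts["12"] == counts["total"]

    def test_entropy_bounds_hold_for_random_compositions(self):
        st, labels = labeled_two_cluster([20, 0, 0], n_per_cluster=6)
        rng = np.random.default_rng(4)
        for _ in range(25):
            pairs = rng.integers(0, 12, size=(rng.integers(1, 40), 2))
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            if len(pairs) == 0:
                continue
            h = analysis.bond_exchange_entropy(pairs, st.chain_id, labels)
            assert 0.0 <= h <= np.log(3.0) + 1e-12


class TestContacts:
    def test_cutoff_boundary(self):
        st, labels = labeled_two_cluster([300, 0, 0], n_per_cluster=1)
        st.positions[1] = st.positions[0] + [22.0, 0, 0]
        assert analysis.contact_count(st)["total"] == 1
        st.positions[1] = st.positions[0] + [23.0, 0, 0]
        assert analysis.contact_count(st)["total"] == 0

    def test_default_cutoff_matches_reference(self):
        assert analysis.CONTACT_CUTOFF == 22.44

    def test_intrachain_neighbors_excluded(self):
        # backbone neighbors (1 and 2 bonds apart) are not contacts
        st = SystemState(
            positions=np.array([[0., 0, 0], [10., 0, 0], [20., 0, 0],
                                [30., 0, 0], [40., 0, 0]]) + 100.0,
            velocities=np.zeros((5, 3)),
            box_length=300.0,
            chain_id=np.zeros(5, dtype=int),
            bead_index=np.arange(5),
            flavor=np.zeros(5, dtype=np.int8),
        )
        # pairs within 22.44: (i, i+1) at 10 and (i, i+2) at 20 -> excluded
        assert analysis.contact_count(st)["total"] == 0

    def test_symmetric_fused_state_has_balanced_intracluster_contacts(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            pts = rng.normal(scale=15.0, size=(60, 3)) + 150.0
            n = len(pts)
            st = SystemState(
                positions=pts, velocities=np.zeros((n, 3)), box_length=300.0,
                chain_id=np.arange(n), bead_index=np.zeros(n, dtype=int),
                flavor=np.zeros(n, dtype=np.int8),
            )
            labels = np.tile([1, 2], n // 2)  # interleaved: statistically same
            counts = analysis.contact_count(st, labels)
            assert counts["11"] + counts["22"] + counts["12"] == counts["total"]
            assert abs(counts["11"] - counts["22"]) < 0.35 * counts["total"]


class TestConvexHull:
    def test_cube_surface_volume_ratio(self):
        L = 10.0
        corners = np.array([[x, y, z] for x in (0, L)
                            for y in (0, L) for z in (0, L)])
        s, v, ratio = analysis.hull_surface_volume(corners)
        assert s == pytest.approx(6 * L ** 2)
        assert v == pytest.approx(L ** 3)
        assert ratio == pytest.approx(6 / L)

    def test_dense_ball_approaches_sphere_ratio(self, rng):
        R = 30.0
        u = rng.normal(size=(20000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = u * (R * rng.random(20000) ** (1 / 3))[:, None]
        _, _, ratio = analysis.hull_surface_volume(pts)
        assert ratio == pytest.approx(3.0 / R, rel=0.05)

    def test_dilation_halves_ratio(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3))
        _, _, r1 = analysis.hull_surface_volume(pts)
        _, _, r2 = analysis.hull_surface_volume(2 * pts)
        assert r2 == pytest.approx(r1 / 2, rel=1e-9)

    def test_degenerate_input_flagged(self):
        s, v, ratio = analysis.hull_surface_volume(np.zeros((3, 3)))
        assert np.isnan(ratio)
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        assert np.isnan(analysis.hull_surface_volume(coplanar)[2])


class TestBondNetwork:
    def test_two_chains_one_bond(self, dimer):
        g = analysis.bond_network(dimer)
        assert dict(g.degree()) == {0: 1, 1: 1}
        assert analysis.largest_component_fraction(g) == 1.0

    def test_no_bonds_gives_singletons(self, microcluster):
        g = analysis.bond_network(microcluster)
        assert analysis.largest_component_fraction(g) == pytest.approx(0.1)
        np.testing.assert_array_equal(
            analysis.degree_distribution(g), [10])

    def test_multiplicity_collapsed_but_stored(self):
        st, _ = labeled_two_cluster([20, 0, 0], n_per_cluster=1)
        # add two bonds between same chain pair is impossible with 1-bead
        # chains; use a 2-sticker-per-chain construction instead
        n = 4
        st = SystemState(
            positions=np.zeros((n, 3)) + 50.0,
            velocities=np.zeros((n, 3)),
            box_length=200.0,
            chain_id=np.array([0, 0, 1, 1]),
            bead_index=np.array([0, 1, 0, 1]),
            flavor=np.array([FLAVOR_A, FLAVOR_A, FLAVOR_B, FLAVOR_B],
                            dtype=np.int8),
        )
        st.bond_partner[:] = [2, 3, 0, 1]
        g = analysis.bond_network(st)
        assert g.number_of_edges() == 1
        assert g[0][1]["multiplicity"] == 2

    def test_saturated_cluster_every_chain_connected(self, ff, thermo):
        from condfuse.protocols import anneal_bonded_cluster
        from condfuse.system_builder import pack_compact_cluster
        from condfuse.dynamics import run

        st = pack_compact_cluster(3, box_length=300.0, cluster_radius=26.0,
                                  seed=31)
        run(st, ff, 500, thermo=thermo, seed=31, bond_updates=False,
            force_cap=20.0)
        anneal_bonded_cluster(st, ff, thermo=thermo, seed=32)
        g = analysis.bond_network(st)
        degrees = dict(g.degree())
        assert all(d >= 1 for d in degrees.values())


class TestRadialProfile:
    def test_uniform_occupancy_is_flat(self):
        rng = np.random.default_rng(6)
        n = 40
        st = SystemState(
            positions=rng.normal(scale=20.0, size=(n, 3)) + 150.0,
            velocities=np.zeros((n, 3)),
            box_length=300.0,
            chain_id=np.arange(n),
            bead_index=np.zeros(n, dtype=int),
            flavor=np.tile([FLAVOR_A, FLAVOR_B], n // 2).astype(np.int8),
        )
        pairs = np.arange(n).reshape(-1, 2)
        st.bond_partner[pairs[:, 0]] = pairs[:, 1]
        st.bond_partner[pairs[:, 1]] = pairs[:, 0]
        profile = analysis.radial_occupancy_profile(st, n_shells=4)
        np.testing.assert_allclose(profile, 1.0)

    def test_core_bonded_surface_free_profile(self):
        # constructed ground truth: bonded stickers near the centroid,
        # free stickers on a far shell
        inner = np.random.default_rng(7).normal(scale=5.0, size=(20, 3))
        outer_dir = np.random.default_rng(8).normal(size=(20, 3))
        outer = 40.0 * outer_dir / np.linalg.norm(outer_dir, axis=1)[:, None]
        pts = np.vstack([inner, outer]) + 150.0
        n = len(pts)
        st = SystemState(
            positions=pts, velocities=np.zeros((n, 3)), box_length=300.0,
            chain_id=np.arange(n), bead_index=np.zeros(n, dtype=int),
            flavor=np.tile([FLAVOR_A, FLAVOR_B], n // 2).astype(np.int8),
        )
        for k in range(0, 20, 2):
            st.bond_partner[k], st.bond_partner[k + 1] = k + 1, k
        profile = analysis.radial_occupancy_profile(st, n_shells=2)
        assert profile[0] == pytest.approx(1.0)
        assert profile[1] == pytest.approx(0.0)

    def test_shell_average_recovers_global_occupancy(self, microcluster):
        st = microcluster
        stickers = np.flatnonzero(st.sticker_mask)
        st.bond_partner[stickers[0]] = stickers[1]
        st.bond_partner[stickers[1]] = stickers[0]
        profile = analysis.radial_occupancy_profile(st, n_shells=5)
        # equal-count shells: the mean of shell occupancies equals the
        # global occupancy
        assert np.mean(profile) == pytest.approx(
            analysis.sticker_occupancy(st), abs=1e-9)
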