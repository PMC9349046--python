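"""A-step selections checked against exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

import genomepop as gp
from genomepop.assignment import best_cluster_combo, round_half_away


def make_population(seg, coords, radius=100.0, geometry=None):
    geometry = geometry or gp.NuclearGeometry.sphere(5000.0)
    return gp.StructurePopulation(
        np.asarray(coords, dtype=float), np.full(seg.N, radius), seg, geometry
    )


@pytest.fixture
def seg2():
    """One diploid chromosome of 2 bins: beads 0,1 = copy 0; 2,3 = copy 1."""
    return gp.segment_genome({"c1": 400_000}, 200_000)


def hic(seg, entries):
    A = np.zeros((seg.H, seg.H))
    for I, J, p in entries:
        A[I, J] = A[J, I] = p
    return gp.ContactProbabilityMatrix(A, seg)


class TestContacts:
    def test_full_probability_activates_every_structure(self, seg2, rng):
        S = 10
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 1000)
        W = gp.assign_contacts(hic(seg2, [(0, 1, 1.0)]), X, theta=0.5)
        assert len(W) == S
        assert set(W[:, 0]) == set(range(S))
        # each activation is the argmin copy pair of its structure
        for s, i, j in W:
            combos = [(a, b) for a in (0, 2) for b in (1, 3)]
            d = {c: np.linalg.norm(X.coordinates[s, c[0]] - X.coordinates[s, c[1]]) for c in combos}
            assert (i, j) == min(combos, key=lambda c: d[c])

    def test_below_threshold_gives_no_activation(self, seg2, rng):
        X = make_population(seg2, rng.random((4, seg2.N, 3)) * 1000)
        W = gp.assign_contacts(hic(seg2, [(0, 1, 0.05)]), X, theta=0.1)
        assert len(W) == 0

    def test_selection_matches_brute_force(self, seg2, rng):
        """S=4, a=0.5: the chosen (structure, copy pair) activations minimize
        the total distance over all ways of picking k structures with one
        copy pair each (exhaustive enumeration)."""
        S, a = 4, 0.5
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
        W = gp.assign_contacts(hic(seg2, [(0, 1, a)]), X, theta=0.1)
        k = max(1, round_half_away(a * S))
        assert len(W) == k
        combos = [(i, j) for i in (0, 2) for j in (1, 3)]
        d = np.array(
            [[np.linalg.norm(X.coordinates[s, i] - X.coordinates[s, j]) for (i, j) in combos] for s in range(S)]
        )
        best_total = min(
            sum(min(d[s]) for s in struct_choice)
            for struct_choice in itertools.combinations(range(S), k)
        )
        chosen_total = sum(
            np.linalg.norm(X.coordinates[s, i] - X.coordinates[s, j]) for s, i, j in W
        )
        assert chosen_total == pytest.approx(best_total)

    def test_activation_count_invariant(self, seg2, rng):
        S = 7
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 1000)
        for a in (0.04, 0.2, 0.5, 0.77, 1.0):
            W = gp.assign_contacts(hic(seg2, [(0, 1, a)]), X, theta=0.01)
            assert len(W) == max(1, round_half_away(a * S))


class TestLamina:
    def damid(self, seg, values):
        return gp.LaminaContactProfile(np.asarray(values, dtype=float), seg)

    def test_full_probability_activates_all_copies(self, seg2, rng):
        S = 3
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 1000)
        V = gp.assign_lamina(self.damid(seg2, [1.0, 0.0]), X, lam=0.5)
        # bin 0 has beads 0 (copy 0) and 2 (copy 1) in all 3 structures
        assert len(V) == S * 2
        assert set(V[:, 1]) == {0, 2}

    def test_zero_probability_activates_none(self, seg2, rng):
        X = make_population(seg2, rng.random((3, seg2.N, 3)) * 1000)
        V = gp.assign_lamina(self.damid(seg2, [0.0, 0.0]), X, lam=0.5)
        assert len(V) == 0

    def test_outermost_candidates_match_brute_force(self, seg2, rng):
        S, e = 3, 0.5
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
        V = gp.assign_lamina(self.damid(seg2, [e, 0.0]), X, lam=0.1)
        k = round_half_away(e * S * 2)
        assert len(V) == k
        rnorm = gp.radial_norm(X.coordinates, X.geometry)
        cands = [(s, b) for s in range(S) for b in (0, 2)]
        expected = set(sorted(cands, key=lambda c: -rnorm[c[0], c[1]])[:k])
        assert {tuple(row) for row in V} == expected


class TestRadialTargets:
    def test_fixed_point_has_zero_residuals(self, seg2, rng):
        S = 5
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
        fish = gp.radial_distance_distributions(X, [0], units="radial")
        idx, targets, tols = gp.assign_radial_targets(fish, X, tol=0.1)
        rnorm = gp.radial_norm(X.coordinates, X.geometry)
        model = np.array([rnorm[s, b] for s, b in idx])
        np.testing.assert_allclose(model, targets, rtol=1e-12)

    def test_rank_pairing_beats_alternative(self, seg2):
        """S=2: the rank-to-rank match minimizes total displacement over
        both possible pairings."""
        coords = np.zeros((2, 4, 3))
        coords[0, 0] = [1000, 0, 0]
        coords[0, 2] = [200, 0, 0]
        coords[1, 0] = [3000, 0, 0]
        coords[1, 2] = [500, 0, 0]
        X = make_population(seg2, coords)
        zmax = np.array([0.25, 0.55])
        zmin = np.array([0.01, 0.02])
        fish = gp.RadialDistributionSet({0: (zmax, zmin)}, "radial", X.segmentation)
        idx, targets, _ = gp.assign_radial_targets(fish, X, tol=0.05)
        rnorm = gp.radial_norm(X.coordinates, X.geometry)
        smax = {s: max(rnorm[s, 0], rnorm[s, 2]) for s in (0, 1)}
        chosen = sum(abs(smax[s] - t) for (s, b), t in zip(idx, targets) if t in zmax)
        for perm in itertools.permutations(range(2)):
            alt = sum(abs(smax[s] - np.sort(zmax)[r]) for r, s in enumerate(perm))
            assert chosen <= alt + 1e-12

    def test_constant_target_restrains_outer_copy_everywhere(self, seg2, rng):
        S = 4
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
        r_star = 0.7
        z = np.full(S, r_star)
        fish = gp.RadialDistributionSet({0: (z, z * 0.1)}, "radial", X.segmentation)
        idx, targets, _ = gp.assign_radial_targets(fish, X, tol=0.05)
        rnorm = gp.radial_norm(X.coordinates, X.geometry)
        outer = {(s, [0, 2][int(np.argmax(rnorm[s, [0, 2]]))]) for s in range(S)}
        got = {tuple(row) for row, t in zip(idx, targets) if t == r_star}
        assert got == outer

    def test_length_mismatch_rejected(self, seg2, rng):
        X = make_population(seg2, rng.random((3, seg2.N, 3)) * 1000)
        fish = gp.RadialDistributionSet(
            {0: (np.array([0.1, 0.2]), np.array([0.05, 0.1]))}, "radial", seg2
        )
        with pytest.raises(gp.GenomePopError, match="length"):
            gp.assign_radial_targets(fish, X, tol=0.1)


class TestPairwiseTargets:
    def test_fixed_point_and_single_structure(self, seg2, rng):
        for S in (1, 4):
            X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
            fish = gp.pairwise_distance_distributions(X, [(0, 1)])
            idx, targets, _ = gp.assign_pairwise_targets(fish, X, tol=0.1)
            assert len(idx) == 2 * S  # max and min restrained per structure
            d = np.array(
                [np.linalg.norm(X.coordinates[s, i] - X.coordinates[s, j]) for s, i, j in idx]
            )
            np.testing.assert_allclose(d, targets, rtol=1e-12)

    def test_rank_matching_is_optimal_transport(self, seg2, rng):
        """S=3: total |model - target| under rank matching is minimal over
        all 3! structure-to-target pairings."""
        S = 3
        X = make_population(seg2, rng.random((S, seg2.N, 3)) * 2000)
        zmax = np.sort(rng.random(S) * 3000)
        zmin = zmax * 0.1
        fish = gp.PairwiseDistributionSet({(0, 1): (zmax, zmin)}, "nm", X.segmentation)
        idx, targets, _ = gp.assign_pairwise_targets(fish, X, tol=0.05)
        combos = [(i, j) for i in (0, 2) for j in (1, 3)]
        dmax = np.array(
            [max(np.linalg.norm(X.coordinates[s, i] - X.coordinates[s, j]) for i, j in combos) for s in range(S)]
        )
        chosen = sum(
            abs(np.linalg.norm(X.coordinates[s, i] - X.coordinates[s, j]) - t)
            for (s, i, j), t in zip(idx, targets)
            if t in zmax
        )
        best = min(
            sum(abs(dmax[s] - zmax[r]) for r, s in enumerate(perm))
            for perm in itertools.permutations(range(S))
        )
        assert chosen <= best + 1e-9


class TestSprite:
    def test_adjacent_pair_assigned_to_hosting_structure(self, seg2):
        # all four bead positions well separated in both structures, except
        # the copy-0 beads of both bins in structure 0, which are adjacent
        coords = np.array(
            [
                [[0, 0, 0], [150, 0, 0], [3000, 0, 0], [0, 3000, 0]],
                [[-3000, 0, 0], [3000, 0, 0], [0, -3000, 0], [0, 3000, 0]],
            ],
            dtype=float,
        )
        X = make_population(seg2, coords)
        sprite = gp.SpriteClusterSet([(0, 1)], seg2)
        R = gp.assign_sprite(sprite, X, rho=0.2)
        s, members, r_c = R[0]
        assert s == 0 and set(members) == {0, 1}

    def test_coincident_members_zero_residual_at_full_density(self, seg2):
        coords = np.zeros((1, 4, 3))
        X = make_population(seg2, coords)
        sprite = gp.SpriteClusterSet([(0, 1)], seg2)
        R = gp.assign_sprite(sprite, X, rho=1.0)
        s, members, r_c = R[0]
        d = max(
            np.linalg.norm(X.coordinates[s, m] - X.coordinates[s, list(members)].mean(axis=0))
            for m in members
        )
        assert d == 0.0

    def test_combo_matches_exhaustive_search(self, rng):
        seg = gp.segment_genome({"c1": 600_000}, 200_000)  # 3 bins, 8 combos
        S = 3
        X = make_population(seg, rng.random((S, seg.N, 3)) * 2000)
        combos, scores = best_cluster_combo(X, (0, 1, 2))
        for s in range(S):
            best = np.inf
            for combo in itertools.product(*[seg.beads_of_bin(I) for I in (0, 1, 2)]):
                pts = X.coordinates[s, list(combo)]
                sc = np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()
                best = min(best, sc)
            assert scores[s] == pytest.approx(best)

    def test_cluster_radius_closed_form(self):
        # n equal beads of radius r at density rho: r_c = r * (n/rho)^(1/3)
        r_c = gp.assignment.cluster_radius(np.full(4, 100.0), rho=0.5)
        assert r_c == pytest.approx(100.0 * (4 / 0.5) ** (1 / 3))
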