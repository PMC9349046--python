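"""Structural observables: recapitulation tensors and the feature suite."""

import numpy as np
import pytest

import genomepop as gp


def diploid_seg(n_bins=2, n_chrom=1):
    return gp.segment_genome(
        {f"c{k}": n_bins * 200_000 for k in range(n_chrom)}, 200_000
    )


def pop(seg, coords, radius=100.0, geometry=None):
    geometry = geometry or gp.NuclearGeometry.sphere(5000.0)
    return gp.StructurePopulation(
        np.asarray(coords, dtype=float), np.full(seg.N, radius), seg, geometry
    )


class TestSimulateContactMatrix:
    def test_one_copy_pair_contact_everywhere_gives_half(self):
        seg = diploid_seg(2)  # beads: 0,1 copy 0; 2,3 copy 1
        S = 3
        coords = np.zeros((S, 4, 3))
        coords[:, 0] = [0, 0, 0]
        coords[:, 1] = [300, 0, 0]  # copy-0 pair in contact (d=300 <= 400)
        coords[:, 2] = [3000, 0, 0]
        coords[:, 3] = [-3000, 0, 0]
        A = gp.simulate_contact_matrix(pop(seg, coords)).matrix
        assert A[0, 1] == pytest.approx(0.5)  # 1 copy pair / min(CN)=2 / S

    def test_no_contacts_gives_zero_matrix(self):
        seg = diploid_seg(2)
        coords = np.array([[[0, 0, 0], [2000, 0, 0], [0, 2000, 0], [0, 0, 2000]]] , dtype=float)
        A = gp.simulate_contact_matrix(pop(seg, coords)).matrix
        assert A.sum() == 0.0

    def test_both_homolog_pairs_clip_to_one(self):
        seg = diploid_seg(2)
        coords = np.zeros((2, 4, 3))  # everything coincident: 4 copy pairs in contact
        A = gp.simulate_contact_matrix(pop(seg, coords)).matrix
        assert A[0, 1] == 1.0  # raw 4/2 = 2.0, clipped

    def test_diagonal_ignored(self):
        seg = diploid_seg(2)
        coords = np.zeros((1, 4, 3))
        A = gp.simulate_contact_matrix(pop(seg, coords)).matrix
        assert np.all(np.diag(A) == 0.0)


class TestSimulateDamid:
    def test_center_and_envelope_extremes(self):
        seg = diploid_seg(2)
        geo = gp.NuclearGeometry.sphere(2000.0)
        center = pop(seg, np.zeros((2, 4, 3)), radius=100.0, geometry=geo)
        assert gp.simulate_damid_profile(center).values.sum() == 0.0
        on_env = np.zeros((2, 4, 3))
        on_env[:, :, 0] = 1999.0
        outer = pop(seg, on_env, radius=100.0, geometry=geo)
        assert np.all(gp.simulate_damid_profile(outer).values == 1.0)

    def test_shell_boundary_is_inclusive(self):
        seg = diploid_seg(2)
        geo = gp.NuclearGeometry.sphere(2000.0)
        shell = (1 - 0.05) * 2000.0 - 100.0  # = 1800
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = shell  # exactly on the shell boundary
        e = gp.simulate_damid_profile(pop(seg, coords, radius=100.0, geometry=geo)).values
        assert np.all(e == 1.0)

    def test_paper_variant_uses_b_for_z(self):
        seg = diploid_seg(2)
        geo = gp.NuclearGeometry((2000.0, 1500.0, 1000.0))
        coords = np.zeros((1, 4, 3))
        coords[0, :, 2] = 1300.0  # outside c-shell, inside b-shell
        p = pop(seg, coords, radius=100.0, geometry=geo)
        assert np.all(gp.simulate_damid_profile(p, z_semiaxis="c").values == 1.0)
        assert np.all(gp.simulate_damid_profile(p, z_semiaxis="b").values == 0.0)


class TestDistanceDistributions:
    def test_identical_copies_give_equal_max_min(self, rng):
        seg = diploid_seg(2)
        half = rng.uniform(-500, 500, (3, 2, 3))
        coords = np.concatenate([half, half], axis=1)  # copies coincide
        rad = gp.radial_distance_distributions(pop(seg, coords), [0, 1])
        for I in (0, 1):
            np.testing.assert_allclose(rad.distributions[I][0], rad.distributions[I][1])

    def test_single_structure_lists_have_length_one(self, rng):
        seg = diploid_seg(2)
        X = pop(seg, rng.uniform(-500, 500, (1, 4, 3)))
        pw = gp.pairwise_distance_distributions(X, [(0, 1)])
        assert len(pw.distributions[(0, 1)][0]) == 1

    def test_extrema_match_enumeration(self, rng):
        seg = diploid_seg(2)
        coords = rng.uniform(-800, 800, (4, 4, 3))
        X = pop(seg, coords)
        pw = gp.pairwise_distance_distributions(X, [(0, 1)])
        zmax, zmin = pw.distributions[(0, 1)]
        expected_max, expected_min = [], []
        for s in range(4):
            d = [np.linalg.norm(coords[s, i] - coords[s, j]) for i in (0, 2) for j in (1, 3)]
            expected_max.append(max(d))
            expected_min.append(min(d))
        np.testing.assert_allclose(zmax, np.sort(expected_max))
        np.testing.assert_allclose(zmin, np.sort(expected_min))


class TestSpritePresence:
    def test_coincident_members_present(self):
        seg = diploid_seg(2)
        X = pop(seg, np.zeros((2, 4, 3)))
        sp = gp.SpriteClusterSet([(0, 1)], seg)
        assert gp.sprite_presence(X, sp, rho=0.5)[0] == 1

    def test_separated_members_absent(self):
        seg = diploid_seg(2)
        coords = np.zeros((2, 4, 3))
        coords[:, [0, 2], 0] = -4000.0  # bin 0 beads in one hemisphere
        coords[:, [1, 3], 0] = 4000.0  # bin 1 beads in the other
        X = pop(seg, coords)
        sp = gp.SpriteClusterSet([(0, 1)], seg)
        assert gp.sprite_presence(X, sp, rho=0.5)[0] == 0


class TestBasicTracks:
    def test_degenerate_and_trivial_values(self):
        seg = diploid_seg(3)
        geo = gp.NuclearGeometry.sphere(2000.0)
        coords = np.zeros((3, 6, 3))
        coords[:, :, 0] = np.array([100, 300, 500, 100, 300, 500])  # identical structures
        X = pop(seg, coords, geometry=geo)
        tracks = gp.basic_tracks(X)
        # identical structures: sigma = 0 -> delta masked
        assert not tracks["delta_radial"].mask.any()
        # single chromosome: every contact is cis -> ICP = 0
        assert np.nanmax(tracks["icp"].values) == 0.0
        # all radial positions <= 0.5 -> ILF = 1
        assert np.all(tracks["ilf"].values == 1.0)
        assert np.all(tracks["mean_radial"].values <= 0.5)

    def test_delta_zero_when_sigma_uniform(self, rng):
        seg = diploid_seg(4)
        geo = gp.NuclearGeometry.sphere(2000.0)
        base = rng.uniform(-300, 300, (1, 8, 3))
        # same per-structure spread for every bin: sigma identical across bins
        shift = rng.standard_normal((6, 1, 1)) * 50.0
        coords = base + shift  # rigid shifts: all bins share sigma
        X = pop(seg, coords, geometry=geo)
        delta = gp.basic_tracks(X)["delta_radial"].values
        valid = np.isfinite(delta)
        assert np.allclose(delta[valid].mean(), 0.0, atol=0.2)


class TestRgAndCompartment:
    def test_two_beads_rg_is_half_distance(self):
        d = 340.0
        assert gp.radius_of_gyration(np.array([[0, 0, 0], [d, 0, 0]])) == pytest.approx(d / 2)

    def test_printed_formula_hand_case(self):
        """N_AA = N_BB = 1, N_AB = 2 -> T = 4, P(A) = P(B) = 1, score = 2."""
        seg = gp.segment_genome({"c1": 800_000}, 200_000, ploidy={"c1": 1})
        labels = np.array(["A", "A", "B", "B"])
        # chain 0-1-2-3; contacts: (0,1)=AA, (2,3)=BB, (1,2)=AB, (0,3)=AB
        coords = np.zeros((1, 4, 3))
        coords[0, 0] = [0, 0, 0]
        coords[0, 1] = [300, 0, 0]
        coords[0, 2] = [300, 300, 0]
        coords[0, 3] = [0, 300, 0]
        X = pop(seg, coords)
        # verify the intended contact set first (diagonal pairs too far: ~424 > 400)
        A = gp.simulate_contact_matrix(X).matrix
        assert (A > 0).sum() == 2 * 4
        score = gp.compartment_score(X, labels)
        assert score[0] == pytest.approx(2.0)

    def test_no_mixed_contacts_masked(self):
        seg = gp.segment_genome({"c1": 400_000}, 200_000, ploidy={"c1": 1})
        labels = np.array(["A", "A"])
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [300, 0, 0]
        score = gp.compartment_score(pop(seg, coords), labels)
        assert np.isnan(score[0])


class TestBodiesAndTsa:
    def test_two_clumps_give_two_bodies(self):
        """Selected beads in two tight, well-separated clumps: the partition
        must match connected components (2 bodies at the clump centroids)."""
        seg = diploid_seg(10)  # 20 beads; 5% of 10 bins -> 1 bin = 2 beads
        geo = gp.NuclearGeometry.sphere(4000.0)
        rng = np.random.default_rng(2)
        coords = rng.uniform(1500, 3000, (2, 20, 3))  # background far out
        # bin 0 beads (0 and 10) form two separated clumps near the center
        coords[:, 0] = [-1000, 0, 0]
        coords[:, 10] = [1000, 0, 0]
        X = pop(seg, coords, radius=100.0, geometry=geo)
        bodies = gp.predict_bodies(X, "speckle")
        for s in range(2):
            cents = np.sort(bodies.centroids[s][:, 0])
            np.testing.assert_allclose(cents, [-1000.0, 1000.0])

    def test_single_clump_gives_one_body(self):
        seg = diploid_seg(10)
        geo = gp.NuclearGeometry.sphere(4000.0)
        rng = np.random.default_rng(3)
        coords = rng.uniform(1500, 3000, (1, 20, 3))
        coords[0, 0] = [0, 0, 0]
        coords[0, 10] = [150, 0, 0]
        X = pop(seg, coords, radius=100.0, geometry=geo)
        bodies = gp.predict_bodies(X, "speckle")
        assert len(bodies.centroids[0]) == 1

    def test_tsa_hand_case_and_normalization(self):
        seg = diploid_seg(2, n_chrom=1)
        geo = gp.NuclearGeometry.sphere(4000.0)
        coords = np.zeros((1, 4, 3))
        coords[0, 1] = coords[0, 3] = [1000.0, 0, 0]  # bin 1 at 1 um from body
        X = pop(seg, coords, geometry=geo)
        bodies = gp.BodyPartition("speckle", [np.array([[0.0, 0.0, 0.0]])], [[np.array([0])]])
        track = gp.tsa_signal(X, bodies)
        sig0, sig1 = 1.0, np.exp(-4.0)  # e^0 and e^(-R0 * 1 um)
        mean = (sig0 + sig1) / 2
        assert track.values[0] == pytest.approx(np.log(sig0 / mean))
        assert track.values[1] == pytest.approx(np.log(sig1 / mean))
        assert np.exp(track.values).mean() == pytest.approx(1.0)


class TestAssociationFrequencies:
    def test_always_near_body_gives_saf_one(self):
        seg = diploid_seg(2)
        geo = gp.NuclearGeometry.sphere(4000.0)
        coords = np.zeros((2, 4, 3))
        coords[:, 1] = coords[:, 3] = [3000.0, 0, 0]
        X = pop(seg, coords, geometry=geo)
        bodies = gp.BodyPartition(
            "speckle", [np.zeros((1, 3)), np.zeros((1, 3))], [[np.array([0])]] * 2
        )
        saf, laf = gp.association_frequencies(X, bodies)
        assert saf.values[0] == 1.0 and saf.values[1] == 0.0
        assert np.all(laf.values == 0.0)  # nobody beyond radial 0.85... except bin 1
        # bin 1 beads at radial 0.75 < 0.85: LAF 0 as asserted above

    def test_one_copy_half_structures_gives_quarter(self):
        seg = diploid_seg(1)
        geo = gp.NuclearGeometry.sphere(4000.0)
        coords = np.full((4, 2, 3), 3000.0)
        coords[:2, 0] = [0.0, 0.0, 0.0]  # copy 0 near body in 2 of 4 structures
        X = pop(seg, coords, geometry=geo)
        bodies = gp.BodyPartition(
            "speckle", [np.zeros((1, 3))] * 4, [[np.array([0])]] * 4
        )
        saf, _ = gp.association_frequencies(X, bodies)
        assert saf.values[0] == pytest.approx(0.25)


class TestTransAbRatio:
    def test_hand_case_three_a_one_b(self):
        """3 A + 1 B trans neighbors with pseudocount 1 -> ratio 3/2."""
        seg = gp.segment_genome(
            {"c1": 200_000, "c2": 1_000_000}, 200_000, ploidy={"c1": 1, "c2": 1}
        )
        labels = np.array(["B", "A", "A", "A", "B", "B"])
        coords = np.zeros((1, 6, 3))
        coords[0, 0] = [0, 0, 0]  # focal bead on c1
        for k, bead in enumerate((1, 2, 3, 4)):  # 3 A + 1 B within 500 nm
            coords[0, bead] = [200.0 + 10 * k, 0, 0]
        coords[0, 5] = [3000.0, 0, 0]  # B bead out of range
        X = pop(seg, coords)
        track = gp.trans_ab_ratio(X, labels, rescale=False)
        assert track.values[0] == pytest.approx(1.5)
        scaled = gp.trans_ab_ratio(X, labels)
        assert scaled.values[0] == 1.0  # bin 0 has the largest raw ratio

    def test_empty_neighborhood_masked(self):
        seg = gp.segment_genome(
            {"c1": 200_000, "c2": 200_000}, 200_000, ploidy={"c1": 1, "c2": 1}
        )
        labels = np.array(["A", "B"])
        coords = np.zeros((2, 2, 3))
        coords[:, 1] = [4000.0, 0, 0]
        track = gp.trans_ab_ratio(pop(seg, coords), labels)
        assert not track.mask.any()


def test_track_writers_smoke(tmp_path, rng):
    seg = diploid_seg(3)
    track = gp.FeatureTrack("demo", rng.random(seg.H))
    gp.features.write_track_bedgraph(track, seg, tmp_path / "t.bedgraph")
    gp.features.write_tracks_tsv({"demo": track}, seg, tmp_path / "t.tsv")
    assert len((tmp_path / "t.bedgraph").read_text().splitlines()) == seg.H
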