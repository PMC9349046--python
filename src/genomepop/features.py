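"""Structural observables computed from a structure population.

Two families live here: the *input recapitulation* tensors (simulated Hi-C
contact matrix, lamina DamID profile, FISH distance distributions, SPRITE
presence flags), used to verify that an optimized population statistically
reproduces its inputs, and the *gene microenvironment* feature suite (mean
radial position, cell-to-cell variability, interchromosomal interaction
probability, interior localization frequency, chromatin decompaction,
compartmentalization score, predicted nuclear bodies and TSA-seq-like
proximity signals, speckle/lamina association frequencies, trans A/B ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .genome import GenomePopError, radial_norm
from .io import (
    ContactProbabilityMatrix,
    LaminaContactProfile,
    PairwiseDistributionSet,
    RadialDistributionSet,
    SpriteClusterSet,
    StructurePopulation,
)
from .assignment import best_cluster_combo, cluster_radius
from .optimizer import VIOLATION_CUTOFF

__all__ = [
    "FeatureTrack",
    "BodyPartition",
    "simulate_contact_matrix",
    "simulate_damid_profile",
    "distance_distributions",
    "radial_distance_distributions",
    "pairwise_distance_distributions",
    "sprite_presence",
    "basic_tracks",
    "radius_of_gyration",
    "compartment_score",
    "predict_bodies",
    "tsa_signal",
    "association_frequencies",
    "trans_ab_ratio",
    "write_track_bedgraph",
    "write_tracks_tsv",
    "write_bodies_tsv",
]


@dataclass
class FeatureTrack:
    """Per-haploid-bin feature values with a validity mask."""

    name: str
    values: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None  # True where the value is valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)


@dataclass
class BodyPartition:
    """Predicted nuclear bodies: per structure, centroids and member beads."""

    kind: str  # "speckle" | "lamina_domain"
    centroids: list[np.ndarray]  # per structure, (L_s, 3) nm
    members: list[list[np.ndarray]]  # per structure, per body, bead ids


# ---------------------------------------------------------------------------
# Input recapitulation
# ---------------------------------------------------------------------------

def _contact_pairs(X: StructurePopulation, contact_scale: float) -> list[np.ndarray]:
    """Per structure, the (K, 2) bead pairs with d <= scale * (r_i + r_j)."""
    radii = X.radii
    cutoff = contact_scale * 2.0 * radii.max()
    out = []
    for s in range(X.S):
        pairs = cKDTree(X.coordinates[s]).query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(
                X.coordinates[s, pairs[:, 0]] - X.coordinates[s, pairs[:, 1]], axis=1
            )
            bound = contact_scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
            pairs = pairs[d <= bound]
        out.append(pairs)
    return out


def simulate_contact_matrix(
    X: StructurePopulation, contact_scale: float = 2.0
) -> ContactProbabilityMatrix:
    """Contact probabilities from the population: beads i, j are in contact
    when ``d <= contact_scale * (r_i + r_j)``; per haploid pair,
    ``a_IJ = (1/S) sum_s sum_copypairs w / min(CN(I), CN(J))``, clipped to 1.
    """
    seg = X.segmentation
    H = seg.H
    bin_of = seg.bin_of_bead
    cn = np.array([seg.copy_number(I) for I in range(H)])
    counts = np.zeros(H * H)
    for pairs in _contact_pairs(X, contact_scale):
        if not len(pairs):
            continue
        I = bin_of[pairs[:, 0]]
        J = bin_of[pairs[:, 1]]
        lo, hi = np.minimum(I, J), np.maximum(I, J)
        sel = lo != hi  # diagonal ignored by modeling
        counts += np.bincount(lo[sel] * H + hi[sel], minlength=H * H)
    A = counts.reshape(H, H)
    A = A + A.T
    denom = np.minimum(cn[:, None], cn[None, :]).astype(float)
    A = np.clip(A / (X.S * denom), 0.0, 1.0)
    return ContactProbabilityMatrix(A, seg)


def simulate_damid_profile(
    X: StructurePopulation,
    contact_range: float = 0.05,
    z_semiaxis: str = "c",
) -> LaminaContactProfile:
    """Lamina contact probabilities: a bead is in contact with the lamina
    when it lies on or outside the shell ellipsoid of semiaxes
    ``(1 - c_r) * (a, b, c) - r_i`` (boundary inclusive);
    ``e_I = (1/S) sum_s sum_copies v / CN(I)``.

    ``z_semiaxis="b"`` reproduces a published variant that scales the z term
    by semiaxis b instead of c.
    """
    seg = X.segmentation
    a, b, c = X.geometry.semiaxes
    axes = np.array([a, b, b if z_semiaxis == "b" else c])
    shell = (1.0 - contact_range) * axes[None, :] - X.radii[:, None]
    if np.any(shell <= 0):
        raise GenomePopError("lamina shell axes non-positive; contact_range too large")
    scl = X.coordinates / shell[None, :, :]
    outside = np.einsum("snk,snk->sn", scl, scl) >= 1.0
    v_sum = outside.sum(axis=0)  # per bead over structures
    e = np.zeros(seg.H)
    np.add.at(e, seg.bin_of_bead, v_sum)
    cn = np.array([seg.copy_number(I) for I in range(seg.H)], dtype=float)
    return LaminaContactProfile(e / (X.S * cn), seg)


def radial_distance_distributions(
    X: StructurePopulation, loci, units: str = "radial"
) -> RadialDistributionSet:
    """Per locus, the sorted per-structure max/min radial position over the
    homolog copies (the S maximal and S minimal distances)."""
    seg = X.segmentation
    if units == "radial":
        vals = radial_norm(X.coordinates, X.geometry)
    else:
        vals = np.linalg.norm(X.coordinates, axis=2)
    dists = {}
    for I in loci:
        beads = seg.beads_of_bin(int(I))
        v = vals[:, beads]
        dists[int(I)] = (np.sort(v.max(axis=1)), np.sort(v.min(axis=1)))
    return RadialDistributionSet(dists, units, seg)


def pairwise_distance_distributions(
    X: StructurePopulation, pairs
) -> PairwiseDistributionSet:
    """Per haploid pair, the sorted per-structure max/min distance over the
    CN(I) x CN(J) copy-pair combinations (nm)."""
    seg = X.segmentation
    coords = X.coordinates
    dists = {}
    for I, J in pairs:
        bi = seg.beads_of_bin(int(I))
        bj = seg.beads_of_bin(int(J))
        ii, jj = zip(*[(a, b) for a in bi for b in bj])
        d = np.linalg.norm(coords[:, list(ii)] - coords[:, list(jj)], axis=2)
        dists[(int(I), int(J))] = (np.sort(d.max(axis=1)), np.sort(d.min(axis=1)))
    return PairwiseDistributionSet(dists, "nm", seg)


def distance_distributions(X: StructurePopulation, loci=None, pairs=None, units="radial"):
    """Dispatch to radial and/or pairwise distribution extraction."""
    out = []
    if loci is not None:
        out.append(radial_distance_distributions(X, loci, units))
    if pairs is not None:
        out.append(pairwise_distance_distributions(X, pairs))
    return out[0] if len(out) == 1 else tuple(out)


def sprite_presence(
    X: StructurePopulation, sprite: SpriteClusterSet, rho: float, enum_cap: int = 10
) -> np.ndarray:
    """Presence flag per cluster: 1 iff some structure hosts a copy
    combination whose members all sit within the density radius r_c of their
    centroid (within the 5% violation tolerance)."""
    flags = np.zeros(len(sprite.clusters), dtype=np.int64)
    seg = X.segmentation
    for k, members in enumerate(sprite.clusters):
        r_c = cluster_radius(
            X.radii[[seg.beads_of_bin(int(I))[0] for I in members]], rho
        )
        _, scores = best_cluster_combo(X, members, enum_cap)
        flags[k] = int(np.min(scores) <= r_c * (1.0 + VIOLATION_CUTOFF))
    return flags


# ---------------------------------------------------------------------------
# Microenvironment feature suite
# ---------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray) -> float:
    """Rg of a set of points: sqrt(mean squared distance to the centroid)."""
    pts = np.asarray(coords, dtype=float)
    cm = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - cm) ** 2, axis=1))))


def _per_bin_mean(values_per_bead: np.ndarray, seg) -> np.ndarray:
    """Average a per-bead quantity over homolog copies -> per haploid bin."""
    out = np.zeros(seg.H)
    np.add.at(out, seg.bin_of_bead, values_per_bead)
    cn = np.array([seg.copy_number(I) for I in range(seg.H)], dtype=float)
    return out / cn


def basic_tracks(
    X: StructurePopulation, contact_scale: float = 2.0, window_bp: int = 1_000_000
) -> dict[str, FeatureTrack]:
    """Mean radial position, radial variability delta, ICP, ILF and
    decompaction (sliding-window Rg over a 1-Mb window)."""
    seg = X.segmentation
    S = X.S
    rnorm = radial_norm(X.coordinates, X.geometry)  # (S, N)
    bin_of = seg.bin_of_bead
    chrom_bin = seg.chrom_of_bin

    mean_radial = _per_bin_mean(rnorm.mean(axis=0), seg)

    # delta: per-region std of radial position across the population (copies
    # pooled), normalized by the chromosome-mean std in log2
    sigma = np.zeros(seg.H)
    for I in range(seg.H):
        beads = seg.beads_of_bin(I)
        sigma[I] = np.std(rnorm[:, beads].reshape(-1))
    sigma[sigma < 1e-12] = 0.0  # degenerate (identical positions): masked
    delta = np.full(seg.H, np.nan)
    for c in np.unique(chrom_bin):
        sel = chrom_bin == c
        sbar = sigma[sel].mean()
        if sbar > 0:
            with np.errstate(divide="ignore"):
                delta[sel] = np.log2(np.where(sigma[sel] > 0, sigma[sel] / sbar, np.nan))

    # ICP: trans / (trans + cis) contacts per region over the population
    chrom_bead = seg.chrom_of_bead
    n_inter = np.zeros(seg.H)
    n_total = np.zeros(seg.H)
    for pairs in _contact_pairs(X, contact_scale):
        if not len(pairs):
            continue
        trans = chrom_bead[pairs[:, 0]] != chrom_bead[pairs[:, 1]]
        for col in (0, 1):
            I = bin_of[pairs[:, col]]
            n_total += np.bincount(I, minlength=seg.H)
            n_inter += np.bincount(I[trans], weights=None, minlength=seg.H) if np.any(trans) else 0
    with np.errstate(invalid="ignore", divide="ignore"):
        icp = np.where(n_total > 0, n_inter / n_total, np.nan)

    # ILF: fraction of structures where either copy is in the inner half
    ilf = np.zeros(seg.H)
    for I in range(seg.H):
        beads = seg.beads_of_bin(I)
        ilf[I] = np.mean(np.any(rnorm[:, beads] <= 0.5, axis=1))

    # decompaction: Rg of the +-500 kb window around each bin, averaged over
    # copies and structures
    half = window_bp // 2 // seg.bin_size
    decomp = np.zeros(seg.H)
    coords = X.coordinates
    for I in range(seg.H):
        same = np.nonzero(chrom_bin == chrom_bin[I])[0]
        lo, hi = max(same[0], I - half), min(same[-1], I + half)
        window_bins = np.arange(lo, hi + 1)
        vals = []
        for copy in range(seg.copy_number(I)):
            beads = [seg.beads_of_bin(int(w))[copy] for w in window_bins]
            pts = coords[:, beads]  # (S, W, 3)
            cm = pts.mean(axis=1, keepdims=True)
            vals.append(np.sqrt(np.mean(np.sum((pts - cm) ** 2, axis=2), axis=1)))
        decomp[I] = np.mean(vals)

    return {
        "mean_radial": FeatureTrack("mean_radial", mean_radial, "radial"),
        "delta_radial": FeatureTrack("delta_radial", delta, "log2"),
        "icp": FeatureTrack("icp", icp),
        "ilf": FeatureTrack("ilf", ilf),
        "decompaction": FeatureTrack("decompaction", decomp, "nm"),
    }


def compartment_score(
    X: StructurePopulation,
    labels: np.ndarray,
    contact_scale: float = 2.0,
    normalization: str = "printed",
) -> np.ndarray:
    """Per-structure compartmentalization score from A/B contact counts:
    ``CompScore = log2(2 P(A) P(B) T / N_AB)`` with
    ``P(A) = (2 N_AA + N_AB)/T`` and ``T = N_AA + N_AB + N_BB``.

    ``normalization="half"`` divides P(A), P(B) by 2 (so P(A) + P(B) = 1).
    Structures with N_AB = 0 yield NaN.
    """
    seg = X.segmentation
    lab = np.asarray(labels)
    bead_lab = lab[seg.bin_of_bead]
    scores = np.full(X.S, np.nan)
    for s, pairs in enumerate(_contact_pairs(X, contact_scale)):
        if not len(pairs):
            continue
        li = bead_lab[pairs[:, 0]]
        lj = bead_lab[pairs[:, 1]]
        ok = (li != "") & (lj != "")
        li, lj = li[ok], lj[ok]
        n_aa = int(np.sum((li == "A") & (lj == "A")))
        n_bb = int(np.sum((li == "B") & (lj == "B")))
        n_ab = int(np.sum(li != lj))
        T = n_aa + n_ab + n_bb
        if T == 0 or n_ab == 0:
            continue
        denom = 2.0 * T if normalization == "half" else float(T)
        p_a = (2 * n_aa + n_ab) / denom
        p_b = (2 * n_bb + n_ab) / denom
        scores[s] = np.log2(2.0 * p_a * p_b * T / n_ab)
    return scores


def predict_bodies(
    X: StructurePopulation,
    kind: str = "speckle",
    fraction: float | None = None,
    link_scale: float = 4.0,
    inflation: float = 1.5,
    expansion: int = 2,
    prune: float = 1e-5,
) -> BodyPartition:
    """Predict nuclear body locations via chromatin interaction networks.

    Speckles: the 5% of regions with the lowest population-mean radial
    position; their beads in each structure form a graph with edges where
    ``d_ij <= link_scale * r0``; Markov clustering partitions the graph and
    each partition's geometric center is one body.  Lamina domains: the same
    pipeline on the 15% of beads with the highest radial position selected
    per structure.
    """
    if X.S == 0:
        raise GenomePopError("empty population")
    seg = X.segmentation
    rnorm = radial_norm(X.coordinates, X.geometry)
    r0 = float(X.radii.max())
    cutoff = link_scale * r0
    centroids: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    if kind == "speckle":
        frac = 0.05 if fraction is None else fraction
        mean_radial = _per_bin_mean(rnorm.mean(axis=0), seg)
        n_sel = max(1, int(np.ceil(frac * seg.H)))
        sel_bins = np.argsort(mean_radial, kind="stable")[:n_sel]
        sel_beads_global = np.concatenate([seg.beads_of_bin(int(I)) for I in sel_bins])
    elif kind == "lamina_domain":
        frac = 0.15 if fraction is None else fraction
        sel_beads_global = None
    else:
        raise GenomePopError(f"unknown body kind {kind!r}")

    for s in range(X.S):
        if kind == "speckle":
            beads = np.sort(sel_beads_global)
        else:
            n_sel = max(1, int(np.ceil(frac * X.N)))
            beads = np.sort(np.argsort(-rnorm[s], kind="stable")[:n_sel])
        pts = X.coordinates[s, beads]
        clusters = _markov_clusters(pts, cutoff, inflation, expansion, prune)
        cents, membs = [], []
        for cl in clusters:
            cents.append(pts[cl].mean(axis=0))
            membs.append(beads[cl])
        centroids.append(np.array(cents))
        members.append(membs)
    return BodyPartition(kind, centroids, members)


def _markov_clusters(
    pts: np.ndarray, cutoff: float, inflation: float, expansion: int, prune: float,
    max_iter: int = 100,
) -> list[np.ndarray]:
    """Markov clustering of the geometric graph with edges at d <= cutoff.

    Returns a partition of ``range(len(pts))`` (connected components of the
    nonzero pattern of the MCL limit matrix; singletons allowed).
    """
    n = len(pts)
    if n == 1:
        return [np.array([0])]
    pairs = cKDTree(pts).query_pairs(cutoff, output_type="ndarray")
    M = np.eye(n)  # self-loops
    if len(pairs):
        M[pairs[:, 0], pairs[:, 1]] = 1.0
        M[pairs[:, 1], pairs[:, 0]] = 1.0
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < 1e-8:
            break
    from scipy.sparse.csgraph import connected_components

    adj = (M + M.T) > 0
    _, comp = connected_components(adj, directed=False)
    return [np.nonzero(comp == c)[0] for c in np.unique(comp)]


def tsa_signal(
    X: StructurePopulation, bodies: BodyPartition, decay: float = 4.0
) -> FeatureTrack:
    """TSA-seq-like proximity signal to predicted nuclear bodies:
    ``sig_i = (1/S) sum_s sum_l exp(-decay * d_isl)`` with distances in um
    (decay is per um); homolog copies averaged; the reported track is
    ``log(sig / genome-mean sig)``.
    """
    seg = X.segmentation
    sig_bead = np.zeros(X.N)
    for s in range(X.S):
        cents = bodies.centroids[s]
        if len(cents) == 0:
            continue
        d = np.linalg.norm(
            X.coordinates[s][:, None, :] - cents[None, :, :], axis=2
        ) / 1000.0  # nm -> um
        sig_bead += np.exp(-decay * d).sum(axis=1)
    sig_bead /= X.S
    sig = _per_bin_mean(sig_bead, seg)
    mean_sig = sig.mean()
    with np.errstate(divide="ignore"):
        track = np.log(sig / mean_sig)
    return FeatureTrack(f"tsa_{bodies.kind}", track, "log")


def association_frequencies(
    X: StructurePopulation,
    bodies: BodyPartition,
    saf_threshold: float = 1000.0,
    laf_threshold: float = 0.85,
) -> tuple[FeatureTrack, FeatureTrack]:
    """Speckle and lamina association frequencies.

    SAF_I: fraction of (structure, copy) observations with the distance to
    the nearest predicted body centroid below ``saf_threshold`` nm (default
    1000 nm; 500 nm for the imaging-comparison regime).  LAF_I: fraction
    with radial position above ``laf_threshold`` (default 0.85; the 750-nm
    lamina-distance regime is matched by adjusting the threshold).
    """
    seg = X.segmentation
    rnorm = radial_norm(X.coordinates, X.geometry)
    near = np.zeros(X.N)
    outer = np.zeros(X.N)
    for s in range(X.S):
        cents = bodies.centroids[s]
        if len(cents):
            d = np.linalg.norm(
                X.coordinates[s][:, None, :] - cents[None, :, :], axis=2
            ).min(axis=1)
            near += d < saf_threshold
        outer += rnorm[s] > laf_threshold
    saf = _per_bin_mean(near / X.S, seg)
    laf = _per_bin_mean(outer / X.S, seg)
    return (
        FeatureTrack("saf", saf),
        FeatureTrack("laf", laf),
    )


def trans_ab_ratio(
    X: StructurePopulation,
    labels: np.ndarray,
    radius: float = 500.0,
    pseudocount: float = 1.0,
    rescale: bool = True,
) -> FeatureTrack:
    """Median trans A/B ratio, min-max rescaled to [0, 1].

    For each (copy, structure) observation the trans neighborhood is all
    beads from other chromosomes within ``radius`` nm; the ratio is
    ``n_A / (n_B + pseudocount)``.  Observations with an empty neighborhood
    are skipped; bins with no observation at all are masked.
    """
    seg = X.segmentation
    bead_lab = np.asarray(labels)[seg.bin_of_bead]
    chrom_bead = seg.chrom_of_bead
    ratios: dict[int, list[float]] = {I: [] for I in range(seg.H)}
    for s in range(X.S):
        tree = cKDTree(X.coordinates[s])
        pairs = tree.query_pairs(radius, output_type="ndarray")
        n_a = np.zeros(X.N)
        n_b = np.zeros(X.N)
        n_any = np.zeros(X.N)
        if len(pairs):
            trans = chrom_bead[pairs[:, 0]] != chrom_bead[pairs[:, 1]]
            pairs = pairs[trans]
            for col, other in ((0, 1), (1, 0)):
                i = pairs[:, col]
                lab_o = bead_lab[pairs[:, other]]
                n_any += np.bincount(i, minlength=X.N)
                n_a += np.bincount(i[lab_o == "A"], minlength=X.N)
                n_b += np.bincount(i[lab_o == "B"], minlength=X.N)
        for bead in np.nonzero(n_any > 0)[0]:
            ratios[int(seg.bin_of_bead[bead])].append(
                n_a[bead] / (n_b[bead] + pseudocount)
            )
    values = np.full(seg.H, np.nan)
    for I, vals in ratios.items():
        if vals:
            values[I] = np.median(vals)
    valid = np.isfinite(values)
    if rescale and valid.sum() >= 2:
        lo, hi = values[valid].min(), values[valid].max()
        if hi > lo:
            values[valid] = (values[valid] - lo) / (hi - lo)
    return FeatureTrack("trans_ab_ratio", values, mask=valid)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_track_bedgraph(track: FeatureTrack, seg, path) -> None:
    with open(path, "w") as fh:
        for I, (chrom, start, end) in enumerate(seg.haploid_bins):
            if track.mask is not None and not track.mask[I]:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{float(track.values[I])!r}\n")


def write_tracks_tsv(tracks: dict[str, FeatureTrack], seg, path) -> None:
    names = list(tracks)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(names) + "\n")
        for I, (chrom, start, end) in enumerate(seg.haploid_bins):
            row = [str(tracks[n].values[I]) for n in names]
            fh.write(f"{chrom}\t{start}\t{end}\t" + "\t".join(row) + "\n")


def write_bodies_tsv(bodies: BodyPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("structure\tbody\tx_nm\ty_nm\tz_nm\tn_members\n")
        for s, (cents, membs) in enumerate(zip(bodies.centroids, bodies.members)):
            for b, (cent, mm) in enumerate(zip(cents, membs)):
                fh.write(
                    f"{s}\t{b}\t{float(cent[0])!r}\t{float(cent[1])!r}"
                    f"\t{float(cent[2])!r}\t{len(mm)}\n"
                )
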