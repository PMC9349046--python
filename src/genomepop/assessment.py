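"""Synthetic ground truth, input synthesis/perturbation, and model
assessment statistics.

A simulated structure population serves as the ground truth from which all
four input modalities can be generated; models built from (possibly
perturbed) synthetic inputs are then scored against the truth with
cross-Wasserstein scores, Pearson correlations of predicted tracks,
stratum-adjusted correlation of contact matrices, chi-squared
goodness-of-fit tests, and the overall performance rank (OPR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import (
    BeadGeometry,
    GenomePopError,
    NuclearGeometry,
    bead_radius_from_occupancy,
    radial_norm,
    segment_genome,
)
from .io import (
    ContactProbabilityMatrix,
    InputBundle,
    LatentAssignments,
    SpriteClusterSet,
    StructurePopulation,
)
from .features import (
    pairwise_distance_distributions,
    radial_distance_distributions,
    simulate_contact_matrix,
    simulate_damid_profile,
)
from .optimizer import MinimizeParams, relax_population

__all__ = [
    "GroundTruthSpec",
    "AssessmentReport",
    "generate_ground_truth",
    "ab_labels",
    "simulate_inputs",
    "perturb_hic",
    "truncate_inter",
    "wasserstein_distance",
    "cross_wd_score",
    "pooled_samples",
    "scc",
    "chi2_gof",
    "opr",
    "match_structures",
]


@dataclass
class GroundTruthSpec:
    """Conditions for the simulated ground-truth population.

    ``ab_fraction`` is the fraction of bins labeled A; ``radial_bias`` is
    the logistic steepness pushing B-labeled beads outward (and A inward);
    0 disables the bias.  Bond steps are drawn uniformly from
    ``step_range`` in units of the bead radius r0.
    """

    chrom_sizes: dict[str, int]
    S: int
    semiaxes: tuple[float, float, float]
    bin_size: int = 200_000
    ploidy: dict[str, int] = field(default_factory=dict)
    occupancy: float = 0.40
    ab_fraction: float = 0.5
    radial_bias: float = 0.0
    step_range: tuple[float, float] = (2.0, 4.0)
    territory_packing: float = 1.4
    seed: int = 0
    label_seed: int | None = None  # share labels across replicate seeds

    def __post_init__(self) -> None:
        if not 0 <= self.ab_fraction <= 1:
            raise GenomePopError("ab_fraction must be in [0, 1]")
        if self.S < 2:
            raise GenomePopError("ground truth needs S >= 2")

    def segmentation(self):
        return segment_genome(self.chrom_sizes, self.bin_size, self.ploidy)


def ab_labels(spec: GroundTruthSpec) -> np.ndarray:
    """Blocky A/B labels per haploid bin, deterministic in the spec seed.

    A smoothed random signal per chromosome is thresholded at the
    ``ab_fraction`` quantile, yielding contiguous compartment-like blocks.
    """
    seg = spec.segmentation()
    label_seed = spec.seed if spec.label_seed is None else spec.label_seed
    rng = np.random.default_rng(np.random.SeedSequence((label_seed, 0xAB)))
    chrom_bin = seg.chrom_of_bin
    labels = np.full(seg.H, "B", dtype="U1")
    for c in np.unique(chrom_bin):
        sel = np.nonzero(chrom_bin == c)[0]
        raw = rng.standard_normal(len(sel))
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(raw, kernel, mode="same")
        cut = np.quantile(smooth, 1.0 - spec.ab_fraction)
        labels[sel[smooth >= cut]] = "A"
    return labels


def generate_ground_truth(
    spec: GroundTruthSpec, relax: bool = True
) -> StructurePopulation:
    """Grow each chromosome copy as a territory-confined random walk with a
    label-dependent radial bias, then remove steric clashes.

    Each chromosome copy occupies a territory sphere of radius
    ``r0 * n_beads^(1/3) * territory_packing`` placed uniformly inside the
    nucleus (``territory_packing = 0`` disables territories and lets chains
    wander the whole nucleus), emulating the territorial organization of
    interphase chromosomes.  B-labeled beads accept a candidate position at
    radial norm r with probability ``sigmoid(radial_bias * (r - 0.5))`` and
    A-labeled beads with the mirrored probability, so a positive bias pushes
    B outward and A inward; bias 0 accepts everything at probability 1/2
    (unbiased).
    """
    seg = spec.segmentation()
    geometry = NuclearGeometry(tuple(spec.semiaxes))
    r0 = bead_radius_from_occupancy(geometry, seg.N, spec.occupancy)
    labels = ab_labels(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x6E0)))
    axes = geometry.axes_array()
    inner = axes - r0
    if np.any(inner <= 0):
        raise GenomePopError("nucleus too small for the bead radius (occupancy too high)")
    chrom_bead = seg.chrom_of_bead
    copy_bead = seg.copy_of_bead
    bead_lab = labels[seg.bin_of_bead]
    coords = np.empty((spec.S, seg.N, 3))
    lo, hi = spec.step_range

    def accept_prob(lab: str, r: float) -> float:
        if spec.radial_bias == 0.0:
            return 0.5
        sign = 1.0 if lab == "B" else -1.0 if lab == "A" else 0.0
        return 1.0 / (1.0 + np.exp(-sign * spec.radial_bias * (r - 0.5)))

    chains = []
    for c in np.unique(chrom_bead):
        for cp in np.unique(copy_bead[chrom_bead == c]):
            chains.append(np.nonzero((chrom_bead == c) & (copy_bead == cp))[0])

    for s in range(spec.S):
        for members in chains:
            center, r_terr = None, np.inf
            if spec.territory_packing > 0:
                r_terr = r0 * len(members) ** (1.0 / 3.0) * spec.territory_packing
                r_terr = min(r_terr, 0.95 * float(axes.min()))
                terr_inner = np.maximum(axes - r_terr, 0.05 * axes)
                while True:
                    center = (rng.random(3) * 2.0 - 1.0) * terr_inner
                    if np.sum((center / terr_inner) ** 2) <= 1.0:
                        break
            prev = None
            for bead in members:
                lab = bead_lab[bead]
                pos = None
                for _ in range(40):
                    if prev is None:
                        cand = (rng.random(3) * 2.0 - 1.0) * inner
                        if center is not None:
                            u = rng.standard_normal(3)
                            u /= np.linalg.norm(u)
                            cand = center + u * r_terr * rng.random() ** (1.0 / 3.0)
                        if np.sum((cand / inner) ** 2) > 1.0:
                            continue
                    else:
                        step = rng.uniform(lo, hi) * r0
                        u = rng.standard_normal(3)
                        cand = prev + step * u / np.linalg.norm(u)
                        if np.sum((cand / inner) ** 2) > 1.0:
                            continue
                        if center is not None and np.linalg.norm(cand - center) > r_terr:
                            continue
                    r = float(radial_norm(cand, geometry))
                    if rng.random() < accept_prob(lab, r):
                        pos = cand
                        break
                    pos = cand  # fall back to the last in-envelope candidate
                if pos is None:
                    pos = prev if prev is not None else (rng.random(3) * 2.0 - 1.0) * inner * 0.5
                coords[s, bead] = pos
                prev = pos
    radii = np.full(seg.N, r0)
    pop = StructurePopulation(
        coords, radii, seg, geometry, {"seed": spec.seed, "schedule_step": -1}
    )
    if relax:
        params = MinimizeParams(seed=(spec.seed, 0x6E1), max_iter=150)
        pop, _ = relax_population(pop, LatentAssignments(), params)
    return pop


def simulate_inputs(
    truth: StructurePopulation,
    n_radial: int = 1000,
    n_pairs: int = 1000,
    n_clusters: int = 0,
    seed: int = 0,
    contact_range: float = 0.05,
    contact_scale: float = 2.0,
    cluster_sizes: tuple[int, int] = (2, 5),
) -> InputBundle:
    """Synthesize all four input modalities from a ground-truth population.

    Radial/pairwise FISH targets are random subsets of loci/pairs (capped at
    the number available); SPRITE clusters are sampled as sets of mutually
    proximal beads in randomly chosen structures.
    """
    if truth.S == 0:
        raise GenomePopError("cannot simulate inputs from an empty population")
    seg = truth.segmentation
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51)))
    hic = simulate_contact_matrix(truth, contact_scale)
    damid = simulate_damid_profile(truth, contact_range)

    loci = rng.choice(seg.H, size=min(n_radial, seg.H), replace=False)
    fish_radial = radial_distance_distributions(truth, sorted(int(v) for v in loci))

    all_pairs = [(I, J) for I in range(seg.H) for J in range(I + 1, seg.H)]
    sel = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    fish_pairwise = pairwise_distance_distributions(
        truth, [all_pairs[k] for k in sorted(sel)]
    )

    sprite = None
    if n_clusters > 0:
        from scipy.spatial import cKDTree

        clusters = []
        tries = 0
        while len(clusters) < n_clusters and tries < 20 * n_clusters:
            tries += 1
            s = int(rng.integers(truth.S))
            bead = int(rng.integers(truth.N))
            size = int(rng.integers(cluster_sizes[0], cluster_sizes[1] + 1))
            tree = cKDTree(truth.coordinates[s])
            _, idx = tree.query(truth.coordinates[s, bead], k=size)
            bins = tuple(dict.fromkeys(int(seg.bin_of_bead[i]) for i in np.atleast_1d(idx)))
            if len(bins) >= 2:
                clusters.append(bins)
        sprite = SpriteClusterSet(clusters, seg)
    return InputBundle(hic, damid, fish_radial, fish_pairwise, sprite)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def _trans_mask(seg) -> np.ndarray:
    chrom = seg.chrom_of_bin
    return chrom[:, None] != chrom[None, :]


def perturb_hic(
    hic: ContactProbabilityMatrix, mode: str, factor: float = 2.0
) -> ContactProbabilityMatrix:
    """Scale down inter- or intra-chromosomal contact probabilities by
    ``factor`` (divide by factor); the other block is untouched."""
    if mode not in ("inter", "intra"):
        raise GenomePopError(f"mode must be 'inter' or 'intra', got {mode!r}")
    trans = _trans_mask(hic.segmentation)
    A = hic.matrix.copy()
    sel = trans if mode == "inter" else ~trans
    A[sel] = A[sel] / factor
    return ContactProbabilityMatrix(A, hic.segmentation)


def truncate_inter(
    hic: ContactProbabilityMatrix, theta_inter: float
) -> ContactProbabilityMatrix:
    """Zero all inter-chromosomal entries below ``theta_inter``."""
    trans = _trans_mask(hic.segmentation)
    A = hic.matrix.copy()
    A[trans & (A < theta_inter)] = 0.0
    return ContactProbabilityMatrix(A, hic.segmentation)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def wasserstein_distance(p: np.ndarray, q: np.ndarray) -> float:
    """1-D optimal-transport (earth mover's) distance between two samples:
    the integral of |P - Q| over the value axis."""
    return float(stats.wasserstein_distance(np.asarray(p), np.asarray(q)))


def pooled_samples(dist_set, key) -> np.ndarray:
    """Pool one target's max and min distributions into a single sample."""
    zmax, zmin = dist_set.distributions[key]
    return np.concatenate([np.asarray(zmax), np.asarray(zmin)])


def cross_wd_score(dists1: dict, dists2: dict) -> float:
    """Cross- ("all versus all") Wasserstein score.

    ``dists1`` and ``dists2`` map the same keys to 1-D samples.  Within each
    population, the Wasserstein distance is computed for every unordered
    key pair; the score is the Pearson correlation between the two sets of
    n(n-1)/2 values.
    """
    keys = sorted(dists1)
    if sorted(dists2) != keys:
        raise GenomePopError("cross_wd_score requires identical key sets")
    wd1, wd2 = [], []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            wd1.append(wasserstein_distance(dists1[keys[a]], dists1[keys[b]]))
            wd2.append(wasserstein_distance(dists2[keys[a]], dists2[keys[b]]))
    if np.array_equal(wd1, wd2):
        return 1.0
    return float(stats.pearsonr(wd1, wd2)[0])


def scc(
    A1: np.ndarray,
    A2: np.ndarray,
    segmentation,
    h: int = 0,
    max_dist: int = 50_000_000,
) -> float:
    """Stratum-adjusted correlation coefficient of two cis contact maps.

    Strata are matrix diagonals (genomic separations) pooled across
    chromosomes up to ``max_dist``; each stratum's Pearson correlation is
    weighted by ``N_k * sqrt(var1_k * var2_k)``.  ``h`` is the smoothing
    window half-width (h = 0 means no smoothing).
    """
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    if h > 0:
        from scipy.ndimage import uniform_filter

        size = 2 * h + 1
        A1 = uniform_filter(A1, size=size, mode="nearest")
        A2 = uniform_filter(A2, size=size, mode="nearest")
    chrom = segmentation.chrom_of_bin
    kmax = max(1, max_dist // segmentation.bin_size)
    num, den = 0.0, 0.0
    for k in range(1, kmax + 1):
        x, y = [], []
        for c in np.unique(chrom):
            idx = np.nonzero(chrom == c)[0]
            n = len(idx)
            if k >= n:
                continue
            x.append(np.array([A1[idx[t], idx[t + k]] for t in range(n - k)]))
            y.append(np.array([A2[idx[t], idx[t + k]] for t in range(n - k)]))
        if not x:
            continue
        xv = np.concatenate(x)
        yv = np.concatenate(y)
        if len(xv) < 2 or xv.std() == 0 or yv.std() == 0:
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        w = len(xv) * float(np.sqrt(xv.var() * yv.var()))
        num += w * r
        den += w
    if den == 0:
        raise GenomePopError("no informative strata for SCC")
    return num / den


def chi2_gof(
    model_sample: np.ndarray, reference_sample: np.ndarray, bins: int | None = None
) -> tuple[float, float]:
    """Chi-squared goodness-of-fit of a model sample against a reference.

    Continuous samples are binned (Sturges rule on the pooled sample by
    default) and bins merged until every expected count is at least 5;
    binary samples (values in {0, 1}) use the two categories directly.  A
    category observed in the model but impossible under the reference gives
    an infinite statistic (p = 0); identical samples give p = 1.
    """
    m = np.asarray(model_sample, dtype=float)
    r = np.asarray(reference_sample, dtype=float)
    uniq = np.unique(np.concatenate([m, r]))
    if set(uniq).issubset({0.0, 1.0}):
        obs = np.array([np.sum(m == 0), np.sum(m == 1)], dtype=float)
        ref = np.array([np.sum(r == 0), np.sum(r == 1)], dtype=float)
    else:
        pooled = np.concatenate([m, r])
        nb = bins or int(np.ceil(np.log2(len(pooled)) + 1))
        edges = np.histogram_bin_edges(pooled, bins=nb)
        obs = np.histogram(m, bins=edges)[0].astype(float)
        ref = np.histogram(r, bins=edges)[0].astype(float)
    exp = ref * (obs.sum() / ref.sum())
    # a category observed in the model but impossible under the reference
    # rejects outright (checked before merging dilutes it)
    if np.any((exp == 0) & (obs > 0)):
        return float("inf"), 0.0
    # merge adjacent bins until expected counts reach 5
    o_list, e_list = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= 5:
            o_list.append(o_acc)
            e_list.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if e_list:
            o_list[-1] += o_acc
            e_list[-1] += e_acc
        else:
            o_list, e_list = [o_acc], [e_acc]
    obs = np.array(o_list)
    exp = np.array(e_list)
    sel = exp > 0
    stat = float(np.sum((obs[sel] - exp[sel]) ** 2 / exp[sel]))
    dof = max(1, int(sel.sum()) - 1)
    return stat, float(stats.chi2.sf(stat, dof))


def opr(rank_table: np.ndarray, n_setups: int | None = None) -> np.ndarray:
    """Overall performance rank per setup: ``OPR_s = sum_f (n_setups + 1 -
    rank_f^s)`` over the feature columns (rank 1 = best)."""
    table = np.asarray(rank_table)
    n = n_setups if n_setups is not None else table.shape[0]
    return np.sum(n + 1 - table, axis=1)


# ---------------------------------------------------------------------------
# Imaged-structure matching
# ---------------------------------------------------------------------------

def _interpolate_missing(struct: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN loci along the chain, per coordinate."""
    out = struct.astype(float).copy()
    n = len(out)
    idx = np.arange(n)
    for k in range(3):
        good = np.isfinite(out[:, k])
        if good.sum() == 0:
            raise GenomePopError("structure has no assigned loci")
        out[~good, k] = np.interp(idx[~good], idx[good], out[good, k])
    return out


def match_structures(
    set1: np.ndarray,
    set2: np.ndarray,
    min_coverage: float = 0.8,
    min_regions: int = 10,
) -> list[tuple[int, int, float]]:
    """Best-match table between two sets of single-structure conformations.

    Inputs are ``(n_structures, n_loci, 3)`` arrays; unassigned loci are
    NaN.  Structures failing the coverage filters (fraction of assigned
    loci below ``min_coverage`` or fewer than ``min_regions`` assigned) are
    dropped; remaining gaps are linearly interpolated.  Each surviving
    structure of set1 is matched to the set2 structure maximizing the
    Pearson correlation of min-max normalized flattened distance matrices.

    Returns rows of (index in set1, best index in set2, Pearson r).
    """

    def prepare(structs):
        kept, mats = [], []
        for i, st in enumerate(np.asarray(structs, dtype=float)):
            assigned = np.all(np.isfinite(st), axis=1)
            if assigned.mean() < min_coverage or assigned.sum() < min_regions:
                continue
            full = _interpolate_missing(st)
            D = np.linalg.norm(full[:, None, :] - full[None, :, :], axis=2)
            v = D[np.triu_indices(len(full), k=1)]
            lo, hi = v.min(), v.max()
            v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
            kept.append(i)
            mats.append(v)
        return kept, np.array(mats)

    kept1, m1 = prepare(set1)
    kept2, m2 = prepare(set2)
    if not kept1 or not kept2:
        return []
    # Pearson via standardized dot products
    z1 = (m1 - m1.mean(axis=1, keepdims=True))
    z2 = (m2 - m2.mean(axis=1, keepdims=True))
    z1 /= np.maximum(np.linalg.norm(z1, axis=1, keepdims=True), 1e-30)
    z2 /= np.maximum(np.linalg.norm(z2, axis=1, keepdims=True), 1e-30)
    corr = z1 @ z2.T
    out = []
    for a, i in enumerate(kept1):
        b = int(np.argmax(corr[a]))
        out.append((i, kept2[b], float(corr[a, b])))
    return out


# ---------------------------------------------------------------------------
# Desk-scale benchmark harnesses
# ---------------------------------------------------------------------------

def benchmark_recapitulation(seed: int = 1, n_pairs: int = 51) -> dict[str, float]:
    """Input-recapitulation benchmark: a 2-chromosome x 60-bin diploid
    genome (S = 100) is simulated as ground truth; Hi-C, DamID and
    ``n_pairs`` pairwise FISH distributions are synthesized from it and the
    stepwise hard-EM pipeline is run on those inputs.

    Returns genome-wide Pearson r of the recomputed contact matrix against
    the input over retained entries (``hic_pearson``), Pearson r of the
    recomputed lamina profile (``damid_pearson``), the cross-Wasserstein
    score of the FISH pairwise distributions (``fish_cross_wd``), and the
    final violation fraction (``violation_fraction``).
    """
    from .features import simulate_contact_matrix, simulate_damid_profile
    from .scheduler import RunConfig, run_pipeline

    spec = GroundTruthSpec(
        chrom_sizes={"chrA": 12_000_000, "chrB": 12_000_000},
        S=100,
        semiaxes=(2400.0, 1800.0, 1500.0),
        radial_bias=4.0,
        seed=int(seed) % 2**31,
    )
    truth = generate_ground_truth(spec)
    bundle = simulate_inputs(truth, n_radial=0, n_pairs=n_pairs, seed=spec.seed)
    bundle.fish_radial = None
    cfg = RunConfig(
        chrom_sizes=spec.chrom_sizes,
        semiaxes=spec.semiaxes,
        S=100,
        seed=(int(seed) + 1) % 2**31,
    )
    pop, states = run_pipeline(cfg, bundle)

    A_in = bundle.hic.matrix
    A_out = simulate_contact_matrix(pop).matrix
    theta_final = cfg.schedules["theta"][-1]
    retained = np.triu(np.ones_like(A_in, dtype=bool), k=1) & (A_in >= theta_final)
    hic_r = float(stats.pearsonr(A_in[retained], A_out[retained])[0])
    damid_r = float(
        stats.pearsonr(bundle.damid.values, simulate_damid_profile(pop).values)[0]
    )
    pairs = list(bundle.fish_pairwise.distributions)
    model_pw = pairwise_distance_distributions(pop, pairs)
    fish_score = cross_wd_score(
        {k: pooled_samples(bundle.fish_pairwise, k) for k in pairs},
        {k: pooled_samples(model_pw, k) for k in pairs},
    )
    return {
        "hic_pearson": hic_r,
        "damid_pearson": damid_r,
        "fish_cross_wd": float(fish_score),
        "violation_fraction": float(states[-1].history[-1]),
        "converged": float(all(st.converged for st in states)),
        "n_retained": int(retained.sum()),
        "n_fish_pairs": len(pairs),
    }


def benchmark_intra_perturbation(seed: int = 1) -> dict[str, float]:
    """Perturbation benchmark: a 3-chromosome x 50-bin ground truth with
    radial A/B bias is simulated; its contact matrix is perturbed by halving
    only the intra-chromosomal probabilities, and a model population is
    built from the perturbed matrix alone.  The speckle-proximity track,
    lamina-proximity track and simulated DamID profile of the model are
    correlated against the ground truth's.

    Returns the three Pearson correlations and their minimum.
    """
    from .features import (
        predict_bodies,
        simulate_contact_matrix,
        simulate_damid_profile,
        tsa_signal,
    )
    from .scheduler import RunConfig, run_pipeline

    spec = GroundTruthSpec(
        chrom_sizes={"chrA": 10_000_000, "chrB": 10_000_000, "chrC": 10_000_000},
        S=100,
        semiaxes=(2400.0, 1800.0, 1500.0),
        radial_bias=4.0,
        seed=int(seed) % 2**31,
    )
    truth = generate_ground_truth(spec)
    hic = perturb_hic(simulate_contact_matrix(truth), "intra", 2.0)
    cfg = RunConfig(
        chrom_sizes=spec.chrom_sizes,
        semiaxes=spec.semiaxes,
        S=100,
        seed=(int(seed) + 1) % 2**31,
    )
    pop, _ = run_pipeline(cfg, InputBundle(hic=hic))

    def three_tracks(p):
        return (
            tsa_signal(p, predict_bodies(p, "speckle")).values,
            tsa_signal(p, predict_bodies(p, "lamina_domain")).values,
            simulate_damid_profile(p).values,
        )

    out = {}
    for name, t, m in zip(
        ("son_tsa_pearson", "lamin_tsa_pearson", "damid_pearson"),
        three_tracks(truth),
        three_tracks(pop),
    ):
        out[name] = float(stats.pearsonr(t, m)[0])
    out["min_pearson"] = min(
        out["son_tsa_pearson"], out["lamin_tsa_pearson"], out["damid_pearson"]
    )
    return out


@dataclass
class AssessmentReport:
    """Scores of one or more modeling setups against a ground truth."""

    scores: dict[str, dict[str, float]]  # setup -> feature -> score
    opr_scores: dict[str, float] = field(default_factory=dict)

    def rank_table(self) -> tuple[list[str], list[str], np.ndarray]:
        setups = sorted(self.scores)
        features = sorted({f for sc in self.scores.values() for f in sc})
        table = np.zeros((len(setups), len(features)), dtype=int)
        for fj, f in enumerate(features):
            vals = np.array([self.scores[s].get(f, np.nan) for s in setups])
            order = np.argsort(-vals, kind="stable")  # higher score = better
            for rank, si in enumerate(order, start=1):
                table[si, fj] = rank
        return setups, features, table

    def compute_opr(self) -> None:
        setups, _, table = self.rank_table()
        vals = opr(table)
        self.opr_scores = {s: float(v) for s, v in zip(setups, vals)}
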