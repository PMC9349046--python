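"""The assignment (A) step of the hard-EM optimization.

Given the current structure population, each ensemble observation is allocated
to the single-cell structures and homolog copies that can realize it at the
least cost: Hi-C contacts go to the structures where the closest copy pair is
already nearest, lamina contacts to the outermost (structure, copy)
candidates, FISH distance distributions are rank-matched to the model's
max/min distance distributions, and each SPRITE cluster is hosted by the one
structure with the most compact copy combination.  All selections are
deterministic (stable sorts; ties broken by structure then copy-pair index)
so a run is reproducible bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genome import GenomePopError, radial_norm
from .io import (
    ContactProbabilityMatrix,
    InputBundle,
    LaminaContactProfile,
    LatentAssignments,
    PairwiseDistributionSet,
    RadialDistributionSet,
    SpriteClusterSet,
    StructurePopulation,
)

__all__ = [
    "ThresholdState",
    "assign_contacts",
    "assign_lamina",
    "assign_radial_targets",
    "assign_pairwise_targets",
    "assign_sprite",
    "assign_all",
    "round_half_away",
    "cluster_radius",
]


@dataclass(frozen=True)
class ThresholdState:
    """Per-data-type activation thresholds at one schedule step.

    theta: Hi-C probability cutoff; lam: DamID cutoff; tol: FISH distance
    tolerance as a fraction of the target; rho: SPRITE cluster volume density.
    """

    theta: float = 1.0
    lam: float = 1.0
    tol: float = 1.0
    rho: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1 or not 0 < self.lam <= 1:
            raise GenomePopError(f"theta/lambda must be in (0, 1], got {self}")
        if self.tol <= 0 or not 0 < self.rho <= 1:
            raise GenomePopError(f"tol must be > 0 and rho in (0, 1], got {self}")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (non-negative input)."""
    return int(np.floor(x + 0.5))


def _copy_pairs(seg, I: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    """Bead index arrays for all CN(I)*CN(J) copy-pair combinations, in fixed
    (copy_i, copy_j) lexicographic order."""
    bi = seg.beads_of_bin(I)
    bj = seg.beads_of_bin(J)
    ii, jj = zip(*[(a, b) for a in bi for b in bj])
    return np.array(ii), np.array(jj)


def assign_contacts(
    hic: ContactProbabilityMatrix, X: StructurePopulation, theta: float
) -> np.ndarray:
    """Activate k = max(1, round(a_IJ * S)) contacts for every retained pair
    a_IJ >= theta, choosing the k structures whose closest copy pair is
    currently shortest, and within each structure that argmin copy pair.

    Returns an int array (K, 3) of (structure, bead_i, bead_j).
    """
    seg = X.segmentation
    A = hic.matrix
    S = X.S
    coords = X.coordinates
    out: list[np.ndarray] = []
    I_idx, J_idx = np.nonzero(np.triu(A, k=1) >= theta)
    for I, J in zip(I_idx, J_idx):
        ii, jj = _copy_pairs(seg, int(I), int(J))
        d = np.linalg.norm(coords[:, ii] - coords[:, jj], axis=2)  # (S, nc)
        best_pair = np.argmin(d, axis=1)
        best_d = d[np.arange(S), best_pair]
        k = min(S, max(1, round_half_away(A[I, J] * S)))
        chosen = np.argsort(best_d, kind="stable")[:k]
        rows = np.column_stack([chosen, ii[best_pair[chosen]], jj[best_pair[chosen]]])
        out.append(rows)
    if not out:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def assign_lamina(
    damid: LaminaContactProfile,
    X: StructurePopulation,
    lam: float,
    contact_range: float = 0.05,
) -> np.ndarray:
    """Activate k = round(e_I * S * CN(I)) lamina contacts per retained bin,
    on the (structure, copy) candidates with the largest radial positions.

    ``contact_range`` (c_r) parameterizes the lamina shell used by the
    restraint builder; the ranking itself only needs radial positions.
    Returns an int array (K, 2) of (structure, bead).
    """
    del contact_range
    seg = X.segmentation
    S = X.S
    rnorm = radial_norm(X.coordinates, X.geometry)  # (S, N)
    out: list[np.ndarray] = []
    for I in np.nonzero(damid.values >= lam)[0]:
        beads = seg.beads_of_bin(int(I))
        cn = len(beads)
        k = min(S * cn, round_half_away(damid.values[I] * S * cn))
        if k == 0:
            continue
        # candidates in (structure, copy) order for deterministic ties
        r = rnorm[:, beads].reshape(-1)  # s-major, copy-minor
        order = np.argsort(-r, kind="stable")[:k]
        s_idx = order // cn
        b_idx = np.array(beads)[order % cn]
        out.append(np.column_stack([s_idx, b_idx]))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def _rank_match(model_vals: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Structure order realizing the rank-to-rank (sorted-to-sorted) match:
    returns structure indices s such that model_vals[s] sorted ascending
    aligns with ``targets`` sorted ascending."""
    return np.argsort(model_vals, kind="stable")


def assign_radial_targets(
    fish: RadialDistributionSet, X: StructurePopulation, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-match each locus's model max/min radial distributions to the
    input Z^max / Z^min and emit two-sided targets with tolerance
    ``tol * target``.

    Returns (idx (K,2) of (structure, bead), targets, tolerances).
    """
    seg = X.segmentation
    S = X.S
    if fish.units == "radial":
        vals = radial_norm(X.coordinates, X.geometry)
    else:
        vals = np.linalg.norm(X.coordinates, axis=2)
    idx_rows, targets = [], []
    for I, (zmax, zmin) in fish.distributions.items():
        if len(zmax) != S:
            raise GenomePopError(
                f"radial distribution for bin {I} has length {len(zmax)} != S={S}"
            )
        beads = np.array(seg.beads_of_bin(int(I)))
        v = vals[:, beads]  # (S, CN)
        for kind, z in (("max", zmax), ("min", zmin)):
            arg = np.argmax(v, axis=1) if kind == "max" else np.argmin(v, axis=1)
            extremum = v[np.arange(S), arg]
            order = _rank_match(extremum, z)
            z_sorted = np.sort(z)
            for rank, s in enumerate(order):
                idx_rows.append((s, beads[arg[s]]))
                targets.append(z_sorted[rank])
    if not idx_rows:
        return np.empty((0, 2), dtype=np.int64), np.empty(0), np.empty(0)
    targets_arr = np.array(targets)
    return np.array(idx_rows, dtype=np.int64), targets_arr, tol * targets_arr


def assign_pairwise_targets(
    fish: PairwiseDistributionSet, X: StructurePopulation, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-match each pair's model max/min copy-pair distance distributions
    to the input Z^max / Z^min.

    Returns (idx (K,3) of (structure, bead_i, bead_j), targets, tolerances).
    """
    seg = X.segmentation
    S = X.S
    coords = X.coordinates
    idx_rows, targets = [], []
    for (I, J), (zmax, zmin) in fish.distributions.items():
        if len(zmax) != S:
            raise GenomePopError(
                f"pairwise distribution for pair {I}-{J} has length {len(zmax)} != S={S}"
            )
        ii, jj = _copy_pairs(seg, int(I), int(J))
        d = np.linalg.norm(coords[:, ii] - coords[:, jj], axis=2)  # (S, nc)
        for kind, z in (("max", zmax), ("min", zmin)):
            arg = np.argmax(d, axis=1) if kind == "max" else np.argmin(d, axis=1)
            extremum = d[np.arange(S), arg]
            order = _rank_match(extremum, z)
            z_sorted = np.sort(z)
            for rank, s in enumerate(order):
                idx_rows.append((s, ii[arg[s]], jj[arg[s]]))
                targets.append(z_sorted[rank])
    if not idx_rows:
        return np.empty((0, 3), dtype=np.int64), np.empty(0), np.empty(0)
    targets_arr = np.array(targets)
    return np.array(idx_rows, dtype=np.int64), targets_arr, tol * targets_arr


def cluster_radius(radii: np.ndarray, rho: float) -> float:
    """Target cluster radius at volume density rho: the sphere holding the
    summed member bead volumes at packing fraction rho,
    r_c = (sum_i r_i^3 / rho)^(1/3)."""
    return float((np.sum(np.asarray(radii, dtype=float) ** 3) / rho) ** (1.0 / 3.0))


def best_cluster_combo(
    X: StructurePopulation, members: tuple[int, ...], enum_cap: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per structure, the copy combination minimizing the maximal member
    distance to the combination centroid.

    Returns (combos (S, n) bead indices, scores (S,) of that maximal
    distance).  Exhaustive over all copy combinations for clusters of up to
    ``enum_cap`` members, greedy (member by member, minimizing the running
    score) beyond.
    """
    seg = X.segmentation
    coords = X.coordinates
    S = X.S
    bead_lists = [seg.beads_of_bin(int(I)) for I in members]
    n = len(members)
    if n <= enum_cap:
        combos = np.array(list(itertools.product(*bead_lists)))  # (nc, n)
        pts = coords[:, combos]  # (S, nc, n, 3)
        centroid = pts.mean(axis=2, keepdims=True)
        score = np.linalg.norm(pts - centroid, axis=3).max(axis=2)  # (S, nc)
        best = np.argmin(score, axis=1)
        return combos[best], score[np.arange(S), best]
    # greedy fallback for very large clusters
    chosen = np.empty((S, n), dtype=np.int64)
    scores = np.empty(S)
    for s in range(S):
        picked: list[int] = []
        for beads in bead_lists:
            best_bead, best_score = beads[0], np.inf
            for b in beads:
                trial = picked + [b]
                pts = coords[s, trial]
                sc = np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()
                if sc < best_score:
                    best_bead, best_score = b, sc
            picked.append(best_bead)
            scores[s] = best_score
        chosen[s] = picked
    return chosen, scores


def assign_sprite(
    sprite: SpriteClusterSet,
    X: StructurePopulation,
    rho: float,
    enum_cap: int = 10,
) -> list[tuple[int, tuple[int, ...], float]]:
    """Assign every SPRITE cluster to the single structure hosting its most
    compact copy combination (ties broken by structure index).

    Returns a list of (structure, bead tuple, cluster radius r_c).
    """
    out = []
    for members in sprite.clusters:
        r_c = cluster_radius(X.radii[[X.segmentation.beads_of_bin(int(I))[0] for I in members]], rho)
        combos, scores = best_cluster_combo(X, members, enum_cap)
        s = int(np.argmin(scores))  # argmin takes the first minimum: lowest s
        out.append((s, tuple(int(b) for b in combos[s]), r_c))
    return out


def assign_all(
    bundle: InputBundle,
    X: StructurePopulation,
    thresholds: ThresholdState,
    enum_cap: int = 10,
) -> LatentAssignments:
    """Run every applicable A-step sub-assignment for one threshold state."""
    asg = LatentAssignments()
    if bundle.hic is not None:
        asg.contacts = assign_contacts(bundle.hic, X, thresholds.theta)
    if bundle.damid is not None:
        asg.lamina = assign_lamina(bundle.damid, X, thresholds.lam)
    if bundle.fish_radial is not None:
        asg.radial_idx, asg.radial_target, asg.radial_tol = assign_radial_targets(
            bundle.fish_radial, X, thresholds.tol
        )
        asg.radial_units = bundle.fish_radial.units
    if bundle.fish_pairwise is not None:
        asg.pair_idx, asg.pair_target, asg.pair_tol = assign_pairwise_targets(
            bundle.fish_pairwise, X, thresholds.tol
        )
    if bundle.sprite is not None:
        asg.clusters = assign_sprite(bundle.sprite, X, thresholds.rho, enum_cap)
    return asg
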