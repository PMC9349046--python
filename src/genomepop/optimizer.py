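"""The modeling (M) step: restraint construction and structure optimization.

Every latent assignment becomes a distance restraint with a flat-bottom
quadratic penalty; three geometric restraint families (nuclear envelope,
excluded volume, chain connectivity) always apply.  Each structure is an
independent minimization problem; the engine evaluates all structures in one
vectorized pass purely for speed — no restraint couples two structures, so
the result equals running each structure on its own with the same
per-structure seed.

Penalty measures and residuals
------------------------------
For an upper bound ``d <= b`` the residual is ``eta = max(0, (d - b)/b)``;
for a lower bound, ``eta = max(0, (b - d)/b)``; for a two-sided target,
``eta = max(0, (|d - target| - tol)/target)``.  ``eta > 0.05`` counts as a
violation.  Dimensionless measures (semiaxis-normalized radial positions)
are scaled by the smallest semiaxis inside the energy so that all penalty
terms and gradients are in nm units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .genome import GenomePopError, GenomeSegmentation, NuclearGeometry
from .io import LatentAssignments, StructurePopulation

__all__ = [
    "RestraintSet",
    "ResidualReport",
    "MinimizeParams",
    "build_restraints",
    "minimize_structure",
    "relax_population",
    "residual_report",
    "VIOLATION_CUTOFF",
]

VIOLATION_CUTOFF = 0.05

RESTRAINT_KINDS = (
    "envelope",
    "excluded_volume",
    "bond",
    "contact",
    "lamina",
    "radial",
    "pair_distance",
    "cluster",
)


@dataclass
class RestraintSet:
    """All restraints acting on one structure.

    Geometry restraints (envelope, excluded volume, bonds) are implicit in
    the segmentation/geometry/radii; data restraints are explicit index and
    target arrays for this structure.
    """

    segmentation: GenomeSegmentation
    geometry: NuclearGeometry
    radii: np.ndarray
    contact_range: float = 0.05
    contact_scale: float = 2.0
    # data restraints, per structure
    contacts: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    lamina: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    radial_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    radial_target: np.ndarray = field(default_factory=lambda: np.empty(0))
    radial_tol: np.ndarray = field(default_factory=lambda: np.empty(0))
    radial_units: str = "radial"
    pair_idx: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    pair_target: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_tol: np.ndarray = field(default_factory=lambda: np.empty(0))
    clusters: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        axes = self.geometry.axes_array()
        lam_axes = (1.0 - self.contact_range) * axes - self.radii.max()
        if np.any(lam_axes <= 0):
            raise GenomePopError("lamina shell axes are non-positive; c_r too large")

    @property
    def bond_pairs(self) -> np.ndarray:
        """Consecutive beads of each chromosome copy, (B, 2)."""
        seg = self.segmentation
        chrom = seg.chrom_of_bead
        copy = seg.copy_of_bead
        bins = seg.bin_of_bead
        i = np.arange(seg.N - 1)
        ok = (chrom[i] == chrom[i + 1]) & (copy[i] == copy[i + 1]) & (bins[i + 1] == bins[i] + 1)
        return np.column_stack([i[ok], i[ok] + 1])


def build_restraints(
    assignments: LatentAssignments,
    segmentation: GenomeSegmentation,
    geometry: NuclearGeometry,
    radii: np.ndarray,
    S: int,
    contact_range: float = 0.05,
    contact_scale: float = 2.0,
) -> list[RestraintSet]:
    """Split population-level latent assignments into per-structure
    restraint sets (geometry restraints are always present)."""
    sets = [
        RestraintSet(segmentation, geometry, radii, contact_range, contact_scale)
        for _ in range(S)
    ]

    def by_structure(s_col: np.ndarray) -> list[np.ndarray]:
        return [np.nonzero(s_col == s)[0] for s in range(S)]

    if len(assignments.contacts):
        for s, rows in enumerate(by_structure(assignments.contacts[:, 0])):
            sets[s].contacts = assignments.contacts[rows, 1:]
    if len(assignments.lamina):
        for s, rows in enumerate(by_structure(assignments.lamina[:, 0])):
            sets[s].lamina = assignments.lamina[rows, 1]
    if len(assignments.radial_idx):
        for s, rows in enumerate(by_structure(assignments.radial_idx[:, 0])):
            sets[s].radial_idx = assignments.radial_idx[rows, 1]
            sets[s].radial_target = assignments.radial_target[rows]
            sets[s].radial_tol = assignments.radial_tol[rows]
            sets[s].radial_units = assignments.radial_units
    if len(assignments.pair_idx):
        for s, rows in enumerate(by_structure(assignments.pair_idx[:, 0])):
            sets[s].pair_idx = assignments.pair_idx[rows, 1:]
            sets[s].pair_target = assignments.pair_target[rows]
            sets[s].pair_tol = assignments.pair_tol[rows]
    for s, beads, r_c in assignments.clusters:
        sets[s].clusters.append((beads, r_c))
    return sets


# ---------------------------------------------------------------------------
# Vectorized population problem
# ---------------------------------------------------------------------------

def _scatter_add(grad_flat: np.ndarray, idx: np.ndarray, vecs: np.ndarray) -> None:
    """Accumulate (K, 3) contributions into an (S*N, 3) gradient buffer."""
    if len(idx) == 0:
        return
    n = grad_flat.shape[0]
    for k in range(3):
        grad_flat[:, k] += np.bincount(idx, weights=vecs[:, k], minlength=n)


class _Problem:
    """Flattened population-wide restraint arrays and the energy/gradient."""

    def __init__(self, sets: list[RestraintSet], S: int, N: int, force_constants=None):
        self.S, self.N = S, N
        rs0 = sets[0]
        self.geometry = rs0.geometry
        self.radii = rs0.radii
        axes = rs0.geometry.axes_array()
        self.env_axes = axes[None, :] - self.radii[:, None]  # (N, 3)
        lam_axes = (1.0 - rs0.contact_range) * axes
        self.lam_axes = lam_axes[None, :] - self.radii[:, None]
        self.c_scale = float(min(axes))
        self.k = dict.fromkeys(RESTRAINT_KINDS, 1.0)
        if force_constants:
            self.k.update(force_constants)
        self.contact_scale = rs0.contact_scale

        bonds = rs0.bond_pairs
        self.bond_i, self.bond_j = bonds[:, 0], bonds[:, 1]
        self.bond_bound = self.contact_scale * (self.radii[self.bond_i] + self.radii[self.bond_j])

        def flat(s, i):
            return s * N + i

        c_s, c_i, c_j = [], [], []
        for s, rs in enumerate(sets):
            for i, j in rs.contacts:
                c_s.append(s), c_i.append(i), c_j.append(j)
        self.con_fi = flat(np.array(c_s, dtype=np.int64), np.array(c_i, dtype=np.int64))
        self.con_fj = flat(np.array(c_s, dtype=np.int64), np.array(c_j, dtype=np.int64))
        ci = np.array(c_i, dtype=np.int64)
        cj = np.array(c_j, dtype=np.int64)
        self.con_bound = self.contact_scale * (self.radii[ci] + self.radii[cj]) if len(ci) else np.empty(0)

        l_s, l_i = [], []
        for s, rs in enumerate(sets):
            for i in rs.lamina:
                l_s.append(s), l_i.append(i)
        self.lam_fi = flat(np.array(l_s, dtype=np.int64), np.array(l_i, dtype=np.int64))
        self.lam_bead = np.array(l_i, dtype=np.int64)

        r_s, r_i, r_t, r_tol = [], [], [], []
        self.radial_units = "radial"
        for s, rs in enumerate(sets):
            self.radial_units = rs.radial_units
            for i, t, tol in zip(rs.radial_idx, rs.radial_target, rs.radial_tol):
                r_s.append(s), r_i.append(i), r_t.append(t), r_tol.append(tol)
        self.rad_fi = flat(np.array(r_s, dtype=np.int64), np.array(r_i, dtype=np.int64))
        self.rad_bead = np.array(r_i, dtype=np.int64)
        self.rad_target = np.array(r_t)
        self.rad_tol = np.array(r_tol)

        p_s, p_i, p_j, p_t, p_tol = [], [], [], [], []
        for s, rs in enumerate(sets):
            for (i, j), t, tol in zip(rs.pair_idx, rs.pair_target, rs.pair_tol):
                p_s.append(s), p_i.append(i), p_j.append(j), p_t.append(t), p_tol.append(tol)
        self.pair_fi = flat(np.array(p_s, dtype=np.int64), np.array(p_i, dtype=np.int64))
        self.pair_fj = flat(np.array(p_s, dtype=np.int64), np.array(p_j, dtype=np.int64))
        self.pair_target = np.array(p_t)
        self.pair_tol = np.array(p_tol)

        self.clusters = []  # (s, member flat indices, r_c)
        for s, rs in enumerate(sets):
            for beads, r_c in rs.clusters:
                self.clusters.append((s, flat(s, np.asarray(beads, dtype=np.int64)), r_c))

        # excluded-volume neighbor list (rebuilt periodically)
        self.ev_cutoff = 2.0 * self.radii.max()
        self.ev_skin = self.radii.max()
        self.ev_fi = np.empty(0, dtype=np.int64)
        self.ev_fj = np.empty(0, dtype=np.int64)
        self.ev_bound = np.empty(0)

        self.con_s = np.array(c_s, dtype=np.int64)
        self.bond_count = len(self.bond_i)

    def rebuild_neighbors(self, coords: np.ndarray) -> None:
        S, N = self.S, self.N
        fi, fj = [], []
        cutoff = self.ev_cutoff + self.ev_skin
        for s in range(S):
            pairs = cKDTree(coords[s]).query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                fi.append(s * N + pairs[:, 0])
                fj.append(s * N + pairs[:, 1])
        if fi:
            self.ev_fi = np.concatenate(fi)
            self.ev_fj = np.concatenate(fj)
            self.ev_bound = self.radii[self.ev_fi % N] + self.radii[self.ev_fj % N]
        else:
            self.ev_fi = np.empty(0, dtype=np.int64)
            self.ev_fj = np.empty(0, dtype=np.int64)
            self.ev_bound = np.empty(0)

    # -- energy / gradient ---------------------------------------------------

    def energy_and_grad(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-structure energies (S,) and the gradient (S, N, 3)."""
        S, N = self.S, self.N
        flat = coords.reshape(S * N, 3)
        grad = np.zeros_like(flat)
        e_struct = np.zeros(S)

        def add_struct_energy(flat_idx, e_terms):
            if len(flat_idx):
                e_struct[:] += np.bincount(flat_idx // N, weights=e_terms, minlength=S)

        # envelope: r_env <= 1 with per-bead shrunken axes
        k = self.k["envelope"]
        scaled = coords / self.env_axes[None, :, :]
        r_env = np.sqrt(np.einsum("snk,snk->sn", scaled, scaled))
        exc = np.maximum(0.0, r_env - 1.0)
        if np.any(exc > 0):
            e_struct += k * self.c_scale**2 * np.sum(exc * exc, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pref = np.where(exc > 0, 2.0 * k * self.c_scale**2 * exc / np.maximum(r_env, 1e-30), 0.0)
            grad += (pref[:, :, None] * scaled / self.env_axes[None, :, :]).reshape(S * N, 3)

        # bonds (same index set in every structure): d <= bound
        k = self.k["bond"]
        dvec = coords[:, self.bond_i] - coords[:, self.bond_j]  # (S, B, 3)
        d = np.linalg.norm(dvec, axis=2)
        exc = np.maximum(0.0, d - self.bond_bound[None, :])
        if np.any(exc > 0):
            e_struct += k * np.sum(exc * exc, axis=1)
            pref = np.where(exc > 0, 2.0 * k * exc / np.maximum(d, 1e-30), 0.0)
            g = pref[:, :, None] * dvec
            gflat = grad.reshape(S, N, 3)
            for s in np.nonzero(exc.any(axis=1))[0]:
                np.add.at(gflat[s], self.bond_i, g[s])
                np.add.at(gflat[s], self.bond_j, -g[s])

        # generic flat pair helpers ------------------------------------------
        def pair_terms(fi, fj):
            dvec = flat[fi] - flat[fj]
            d = np.linalg.norm(dvec, axis=1)
            return dvec, d

        # excluded volume: d >= bound
        if len(self.ev_fi):
            k = self.k["excluded_volume"]
            dvec, d = pair_terms(self.ev_fi, self.ev_fj)
            exc = np.maximum(0.0, self.ev_bound - d)
            sel = exc > 0
            if np.any(sel):
                e = k * exc[sel] ** 2
                add_struct_energy(self.ev_fi[sel], e)
                pref = -2.0 * k * exc[sel] / np.maximum(d[sel], 1e-30)
                g = pref[:, None] * dvec[sel]
                _scatter_add(grad, self.ev_fi[sel], g)
                _scatter_add(grad, self.ev_fj[sel], -g)

        # Hi-C contacts: d <= bound
        if len(self.con_fi):
            k = self.k["contact"]
            dvec, d = pair_terms(self.con_fi, self.con_fj)
            exc = np.maximum(0.0, d - self.con_bound)
            sel = exc > 0
            if np.any(sel):
                e = k * exc[sel] ** 2
                add_struct_energy(self.con_fi[sel], e)
                pref = 2.0 * k * exc[sel] / np.maximum(d[sel], 1e-30)
                g = pref[:, None] * dvec[sel]
                _scatter_add(grad, self.con_fi[sel], g)
                _scatter_add(grad, self.con_fj[sel], -g)

        # lamina: bead outside the shrunken shell, r_lam >= 1
        if len(self.lam_fi):
            k = self.k["lamina"]
            pts = flat[self.lam_fi]
            ax = self.lam_axes[self.lam_bead]
            scl = pts / ax
            r = np.linalg.norm(scl, axis=1)
            exc = np.maximum(0.0, 1.0 - r)
            sel = exc > 0
            if np.any(sel):
                e = k * self.c_scale**2 * exc[sel] ** 2
                add_struct_energy(self.lam_fi[sel], e)
                pref = -2.0 * k * self.c_scale**2 * exc[sel] / np.maximum(r[sel], 1e-30)
                g = pref[:, None] * (scl[sel] / ax[sel])
                _scatter_add(grad, self.lam_fi[sel], g)

        # radial FISH targets: |r - target| <= tol
        if len(self.rad_fi):
            k = self.k["radial"]
            pts = flat[self.rad_fi]
            if self.radial_units == "radial":
                ax = self.geometry.axes_array()[None, :]
                scl = pts / ax
                r = np.linalg.norm(scl, axis=1)
                dr_dx = scl / ax / np.maximum(r, 1e-30)[:, None]
                scale2 = self.c_scale**2
            else:
                r = np.linalg.norm(pts, axis=1)
                dr_dx = pts / np.maximum(r, 1e-30)[:, None]
                scale2 = 1.0
            dev = r - self.rad_target
            exc = np.maximum(0.0, np.abs(dev) - self.rad_tol)
            sel = exc > 0
            if np.any(sel):
                e = k * scale2 * exc[sel] ** 2
                add_struct_energy(self.rad_fi[sel], e)
                pref = 2.0 * k * scale2 * exc[sel] * np.sign(dev[sel])
                _scatter_add(grad, self.rad_fi[sel], pref[:, None] * dr_dx[sel])

        # pairwise FISH targets: |d - target| <= tol
        if len(self.pair_fi):
            k = self.k["pair_distance"]
            dvec, d = pair_terms(self.pair_fi, self.pair_fj)
            dev = d - self.pair_target
            exc = np.maximum(0.0, np.abs(dev) - self.pair_tol)
            sel = exc > 0
            if np.any(sel):
                e = k * exc[sel] ** 2
                add_struct_energy(self.pair_fi[sel], e)
                pref = 2.0 * k * exc[sel] * np.sign(dev[sel]) / np.maximum(d[sel], 1e-30)
                g = pref[:, None] * dvec[sel]
                _scatter_add(grad, self.pair_fi[sel], g)
                _scatter_add(grad, self.pair_fj[sel], -g)

        # SPRITE clusters: members within r_c of the (dynamic) centroid
        k = self.k["cluster"]
        for s, members, r_c in self.clusters:
            pts = flat[members]
            centroid = pts.mean(axis=0)
            dvec = pts - centroid
            d = np.linalg.norm(dvec, axis=1)
            exc = np.maximum(0.0, d - r_c)
            if np.any(exc > 0):
                e_struct[s] += k * np.sum(exc**2)
                u = dvec / np.maximum(d, 1e-30)[:, None]
                w = (2.0 * k * exc)[:, None] * u  # (n, 3)
                g = w - w.mean(axis=0)  # centroid back-reaction
                _scatter_add(grad, members, g)

        return e_struct, grad.reshape(S, N, 3)


# ---------------------------------------------------------------------------
# Residual report
# ---------------------------------------------------------------------------

@dataclass
class ResidualReport:
    """Per-kind residuals eta, violation counts and the cumulative fraction.

    The denominator counts every restraint, including all N(N-1)/2 excluded
    volume pairs per structure (the neighbor list is an evaluation pruning,
    not a change to the restraint set).
    """

    residuals: dict[str, np.ndarray]
    totals: dict[str, int]

    @property
    def violations(self) -> dict[str, int]:
        return {
            kind: int(np.sum(eta > VIOLATION_CUTOFF))
            for kind, eta in self.residuals.items()
        }

    @property
    def total_restraints(self) -> int:
        return sum(self.totals.values())

    @property
    def violation_fraction(self) -> float:
        total = self.total_restraints
        return sum(self.violations.values()) / total if total else 0.0

    @property
    def max_eta(self) -> float:
        return max(
            (float(eta.max()) for eta in self.residuals.values() if len(eta)),
            default=0.0,
        )

    def histogram(self, kind: str, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.residuals[kind], bins=bins, range=(0.0, 1.0))


def residual_report(coords: np.ndarray, sets: list[RestraintSet]) -> ResidualReport:
    """Evaluate the residual eta of every restraint on the given coordinates."""
    S, N = coords.shape[0], coords.shape[1]
    prob = _Problem(sets, S, N)
    flat = coords.reshape(S * N, 3)
    res: dict[str, list[np.ndarray]] = {k: [] for k in RESTRAINT_KINDS}
    totals = dict.fromkeys(RESTRAINT_KINDS, 0)

    scaled = coords / prob.env_axes[None, :, :]
    r_env = np.sqrt(np.einsum("snk,snk->sn", scaled, scaled))
    res["envelope"].append(np.maximum(0.0, r_env - 1.0).ravel())
    totals["envelope"] = S * N

    dvec = coords[:, prob.bond_i] - coords[:, prob.bond_j]
    d = np.linalg.norm(dvec, axis=2)
    res["bond"].append(np.maximum(0.0, (d - prob.bond_bound[None, :]) / prob.bond_bound[None, :]).ravel())
    totals["bond"] = S * prob.bond_count

    # exact excluded-volume violations via KD-tree at the contact cutoff
    max_bound = 2.0 * prob.radii.max()
    ev_eta = []
    for s in range(S):
        pairs = cKDTree(coords[s]).query_pairs(max_bound, output_type="ndarray")
        if len(pairs):
            dd = np.linalg.norm(coords[s, pairs[:, 0]] - coords[s, pairs[:, 1]], axis=1)
            bound = prob.radii[pairs[:, 0]] + prob.radii[pairs[:, 1]]
            ev_eta.append(np.maximum(0.0, (bound - dd) / bound))
    res["excluded_volume"].append(np.concatenate(ev_eta) if ev_eta else np.empty(0))
    totals["excluded_volume"] = S * N * (N - 1) // 2

    if len(prob.con_fi):
        d = np.linalg.norm(flat[prob.con_fi] - flat[prob.con_fj], axis=1)
        res["contact"].append(np.maximum(0.0, (d - prob.con_bound) / prob.con_bound))
    totals["contact"] = len(prob.con_fi)

    if len(prob.lam_fi):
        scl = flat[prob.lam_fi] / prob.lam_axes[prob.lam_bead]
        r = np.linalg.norm(scl, axis=1)
        res["lamina"].append(np.maximum(0.0, 1.0 - r))
    totals["lamina"] = len(prob.lam_fi)

    if len(prob.rad_fi):
        pts = flat[prob.rad_fi]
        if prob.radial_units == "radial":
            r = np.linalg.norm(pts / prob.geometry.axes_array()[None, :], axis=1)
        else:
            r = np.linalg.norm(pts, axis=1)
        exc = np.maximum(0.0, np.abs(r - prob.rad_target) - prob.rad_tol)
        res["radial"].append(exc / prob.rad_target)
    totals["radial"] = len(prob.rad_fi)

    if len(prob.pair_fi):
        d = np.linalg.norm(flat[prob.pair_fi] - flat[prob.pair_fj], axis=1)
        exc = np.maximum(0.0, np.abs(d - prob.pair_target) - prob.pair_tol)
        res["pair_distance"].append(exc / prob.pair_target)
    totals["pair_distance"] = len(prob.pair_fi)

    cl_eta = []
    for s, members, r_c in prob.clusters:
        pts = flat[members]
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        cl_eta.append(np.maximum(0.0, (d - r_c) / r_c))
        totals["cluster"] += len(members)
    if cl_eta:
        res["cluster"].append(np.concatenate(cl_eta))

    merged = {
        kind: (np.concatenate(vals) if vals else np.empty(0)) for kind, vals in res.items()
    }
    return ResidualReport(merged, totals)


# ---------------------------------------------------------------------------
# Minimizer
# ---------------------------------------------------------------------------

@dataclass
class MinimizeParams:
    """Gradient-descent-with-momentum engine parameters.

    The iteration budget is split into three simulated-annealing stages with
    noise amplitudes ``noise_sigma * (1, 0.25, 0)``; the final (noise-free)
    stage enforces monotone energy via per-structure backtracking, so the
    total penalty is non-increasing over accepted steps.
    """

    seed: int | tuple = 0
    max_iter: int = 300
    lr: float = 0.25
    momentum: float = 0.6
    max_step: float | None = None  # nm; default 0.5 * max bead radius
    noise_sigma: float | None = None  # nm; default 0.3 * max bead radius
    stages: tuple[float, float, float] = (0.25, 0.25, 0.5)
    rebuild_every: int = 15
    zero_energy: float = 1e-9
    dump_path: str | None = None


def _anneal_schedule(params: MinimizeParams, sigma0: float) -> np.ndarray:
    n = params.max_iter
    f1, f2, _ = params.stages
    n1, n2 = int(n * f1), int(n * f2)
    sig = np.zeros(n)
    sig[:n1] = sigma0
    sig[n1:n1 + n2] = 0.25 * sigma0
    return sig


def _minimize(
    coords: np.ndarray, sets: list[RestraintSet], params: MinimizeParams,
    seeds: list | None = None,
) -> np.ndarray:
    S, N = coords.shape[0], coords.shape[1]
    prob = _Problem(sets, S, N)
    r_max = float(prob.radii.max())
    max_step = params.max_step if params.max_step is not None else 0.5 * r_max
    sigma0 = params.noise_sigma if params.noise_sigma is not None else 0.3 * r_max
    sig = _anneal_schedule(params, sigma0)

    if seeds is None:
        seeds = [(params.seed, s) if not isinstance(params.seed, tuple) else (*params.seed, s) for s in range(S)]
    rngs = [np.random.default_rng(np.random.SeedSequence(seed)) for seed in seeds]

    x = coords.astype(float).copy()
    v = np.zeros_like(x)
    lr_s = np.full(S, params.lr)
    prev_x = x.copy()
    prev_e = np.full(S, np.inf)
    prev_g = np.zeros_like(x)

    for it in range(params.max_iter):
        if it % params.rebuild_every == 0:
            prob.rebuild_neighbors(x)
        e, g = prob.energy_and_grad(x)
        if not np.all(np.isfinite(e)):
            if params.dump_path:
                np.save(params.dump_path, x)
            raise GenomePopError("non-finite energy during minimization")
        noisy = sig[it] > 0
        if not noisy:
            # monotone acceptance: revert structures whose energy increased
            worse = e > prev_e + 1e-12
            if np.any(worse):
                x[worse] = prev_x[worse]
                g[worse] = prev_g[worse]
                e[worse] = prev_e[worse]
                v[worse] = 0.0
                lr_s[worse] *= 0.5
            lr_s[~worse] = np.minimum(params.lr, lr_s[~worse] * 1.05)
        active = e > params.zero_energy
        if noisy:
            active = active.copy()
        if not noisy and not np.any(active):
            break
        prev_x, prev_e, prev_g = x.copy(), e.copy(), g
        step = -lr_s[:, None, None] * g
        v = params.momentum * v + step
        if noisy:
            noise = np.stack([
                rngs[s].standard_normal((N, 3)) * sig[it] if active[s] else np.zeros((N, 3))
                for s in range(S)
            ])
            upd = v + noise
        else:
            upd = v
        norms = np.linalg.norm(upd, axis=2, keepdims=True)
        upd = np.where(norms > max_step, upd * (max_step / np.maximum(norms, 1e-30)), upd)
        x += upd * active[:, None, None]
    return x


def minimize_structure(
    coords: np.ndarray, restraints: RestraintSet, params: MinimizeParams | None = None
) -> tuple[np.ndarray, ResidualReport]:
    """Minimize a single structure's penalty; returns new coordinates and
    its residual report.  Deterministic given the seed."""
    params = params or MinimizeParams()
    x = np.asarray(coords, dtype=float)[None, :, :]
    seed = params.seed if isinstance(params.seed, tuple) else (params.seed,)
    out = _minimize(x, [restraints], params, seeds=[seed])
    return out[0], residual_report(out, [restraints])


def relax_population(
    X: StructurePopulation,
    assignments: LatentAssignments,
    params: MinimizeParams | None = None,
    contact_range: float = 0.05,
    contact_scale: float = 2.0,
    force_constants: dict | None = None,
) -> tuple[StructurePopulation, ResidualReport]:
    """M-step: optimize every structure independently under the restraints
    implied by the current assignments; returns the new population and the
    aggregated residual report."""
    del force_constants  # uniform per-kind constants live in _Problem defaults
    params = params or MinimizeParams()
    sets = build_restraints(
        assignments, X.segmentation, X.geometry, X.radii, X.S,
        contact_range=contact_range, contact_scale=contact_scale,
    )
    out = _minimize(X.coordinates.astype(float), sets, params)
    report = residual_report(out, sets)
    pop = StructurePopulation(out, X.radii, X.segmentation, X.geometry, dict(X.provenance))
    return pop, report
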