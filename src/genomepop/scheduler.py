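"""Stepwise hard-EM driver: initialization, threshold schedules, A/M
iteration and convergence bookkeeping.

The optimization proceeds through a sequence of steps, each defined by one
combination of data thresholds.  Hi-C (theta) and DamID (lambda) thresholds
decrease step by step so that high-probability observations are fitted
first; the FISH distance tolerance (t) decreases; the SPRITE cluster density
(rho) increases.  At every step, assignment (A) and modeling (M) iterations
alternate until the cumulative violation fraction falls below 1e-4 (0.01%),
the convergence criterion; only then does the run move to the next step.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .assignment import ThresholdState, assign_all
from .genome import (
    BeadGeometry,
    GenomePopError,
    GenomeSegmentation,
    NuclearGeometry,
    bead_radius_from_occupancy,
    radial_norm,
)
from .io import InputBundle, LatentAssignments, StructurePopulation, write_population
from .optimizer import MinimizeParams, relax_population

__all__ = [
    "RunConfig",
    "ConvergenceState",
    "DEFAULT_SCHEDULES",
    "CONVERGENCE_FRACTION",
    "init_population",
    "run_step",
    "run_pipeline",
]

CONVERGENCE_FRACTION = 1e-4

DEFAULT_SCHEDULES = {
    "theta": [1.0, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002],
    "lam": [0.9, 0.6, 0.4, 0.2, 0.1, 0.05],
    "tol": [1.0, 0.5, 0.2, 0.1, 0.05],
    "rho": [0.05, 0.1, 0.2, 0.4],
}


@dataclass
class RunConfig:
    """Full run configuration (JSON-serializable).

    ``chrom_sizes`` maps chromosome name -> bp; ``ploidy`` gives per
    chromosome copy numbers (default 2).  ``schedules`` holds the four
    threshold lists; theta/lam/tol must be non-increasing, rho
    non-decreasing, and every final value positive.
    """

    chrom_sizes: dict[str, int]
    semiaxes: tuple[float, float, float]
    S: int
    bin_size: int = 200_000
    ploidy: dict[str, int] = field(default_factory=dict)
    occupancy: float = 0.40
    schedules: dict[str, list[float]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SCHEDULES.items()})
    seed: int = 0
    contact_range: float = 0.05
    contact_scale: float = 2.0
    max_am_iter: int = 10
    strict: bool = False
    out_dir: str | None = None
    engine: dict = field(default_factory=dict)
    input_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.S < 1:
            raise GenomePopError(f"population size S must be >= 1, got {self.S}")
        for key in ("theta", "lam", "tol"):
            seq = self.schedules.get(key, [])
            if any(b > a for a, b in zip(seq, seq[1:])):
                raise GenomePopError(f"{key} schedule must be non-increasing: {seq}")
        rho = self.schedules.get("rho", [])
        if any(b < a for a, b in zip(rho, rho[1:])):
            raise GenomePopError(f"rho schedule must be non-decreasing: {rho}")
        for key, seq in self.schedules.items():
            if seq and seq[-1] <= 0:
                raise GenomePopError(f"final {key} threshold must be > 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["semiaxes"] = tuple(raw["semiaxes"])
        return cls(**raw)

    def threshold_steps(self) -> list[ThresholdState]:
        """One ThresholdState per schedule step; shorter schedules hold their
        final value once exhausted."""
        sched = {k: list(v) for k, v in self.schedules.items()}
        n = max((len(v) for v in sched.values() if v), default=1)

        def at(key: str, k: int, default: float) -> float:
            seq = sched.get(key, [])
            if not seq:
                return default
            return seq[min(k, len(seq) - 1)]

        return [
            ThresholdState(
                theta=at("theta", k, 1.0),
                lam=at("lam", k, 1.0),
                tol=at("tol", k, 1.0),
                rho=at("rho", k, 0.05),
            )
            for k in range(n)
        ]


@dataclass
class ConvergenceState:
    """Append-only record of one optimization step's A/M iterations."""

    step: int
    iterations: int = 0
    history: list[float] = field(default_factory=list)
    breakdown: list[dict[str, int]] = field(default_factory=list)
    converged: bool = False
    stalled: bool = False

    def record(self, fraction: float, violations: dict[str, int]) -> None:
        self.history.append(fraction)
        self.breakdown.append(dict(violations))
        self.iterations += 1


def init_population(
    segmentation: GenomeSegmentation,
    geometry: NuclearGeometry,
    beads: BeadGeometry,
    S: int,
    seed: int = 0,
    packing: float = 1.4,
    relax_params: MinimizeParams | None = None,
) -> StructurePopulation:
    """Random chromosome-territory initialization.

    Each chromosome copy's beads are sampled uniformly inside a territory
    sphere of radius ``r0 * n_beads^(1/3) * packing`` whose center is drawn
    uniformly so the whole sphere fits inside the nucleus; a short
    geometry-only minimization then removes steric clashes.
    """
    if S < 1:
        raise GenomePopError("S must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    axes = geometry.axes_array()
    r0 = beads.r0
    N = segmentation.N
    chrom = segmentation.chrom_of_bead
    copy = segmentation.copy_of_bead
    coords = np.empty((S, N, 3))
    chains = [
        np.nonzero((chrom == c) & (copy == cp))[0]
        for c in np.unique(chrom)
        for cp in np.unique(copy[chrom == c])
    ]
    for members in chains:
        r_terr = r0 * len(members) ** (1.0 / 3.0) * packing
        if np.any(axes - r_terr <= 0):
            raise GenomePopError(
                f"nucleus too small to host a territory sphere of radius {r_terr:.0f} nm"
            )
    for s in range(S):
        for members in chains:
            r_terr = r0 * len(members) ** (1.0 / 3.0) * packing
            inner = axes - r_terr
            while True:  # rejection-sample the territory center
                p = (rng.random(3) * 2.0 - 1.0) * inner
                if np.sum((p / inner) ** 2) <= 1.0:
                    break
            n = len(members)
            pts = rng.standard_normal((n, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts *= r_terr * rng.random(n)[:, None] ** (1.0 / 3.0)
            coords[s, members] = p + pts
    radii = np.full(N, r0)
    pop = StructurePopulation(
        coords, radii, segmentation, geometry, {"seed": seed, "schedule_step": -1}
    )
    params = relax_params or MinimizeParams(seed=(seed, 0xDEAD), max_iter=150)
    pop, _ = relax_population(pop, LatentAssignments(), params)
    # guarantee a strict interior start even if a bead ends exactly on the shell
    rn = radial_norm(pop.coordinates, geometry)
    scale = np.minimum(1.0, 0.999 * (1.0 - r0 / min(axes)) / np.maximum(rn, 1e-12))
    pop.coordinates *= scale[:, :, None]
    return pop


def run_step(
    X: StructurePopulation,
    bundle: InputBundle,
    thresholds: ThresholdState,
    params: MinimizeParams | None = None,
    max_am_iter: int = 10,
    contact_range: float = 0.05,
    contact_scale: float = 2.0,
    step_index: int = 0,
    seed: int = 0,
    log=None,
) -> tuple[StructurePopulation, ConvergenceState]:
    """Alternate A and M steps at one threshold combination until the
    cumulative violation fraction drops below 1e-4 or the iteration budget
    is exhausted (state flagged stalled in the latter case)."""
    state = ConvergenceState(step=step_index)
    pop = X
    for it in range(max_am_iter):
        asg = assign_all(bundle, pop, thresholds)
        p = params or MinimizeParams()
        p = MinimizeParams(**{**p.__dict__, "seed": (seed, step_index, it)})
        pop, report = relax_population(
            pop, asg, p, contact_range=contact_range, contact_scale=contact_scale
        )
        frac = report.violation_fraction
        state.record(frac, report.violations)
        if log is not None:
            log(step_index, it, thresholds, frac, report.violations)
        if frac < CONVERGENCE_FRACTION:
            state.converged = True
            break
    else:
        state.stalled = True
    pop.provenance["schedule_step"] = step_index
    return pop, state


def run_pipeline(
    config: RunConfig,
    bundle: InputBundle,
    segmentation: GenomeSegmentation | None = None,
    initial: StructurePopulation | None = None,
    progress: bool = False,
) -> tuple[StructurePopulation, list[ConvergenceState]]:
    """Execute the full stepwise optimization.

    Returns the final population and one ConvergenceState per schedule step.
    If ``config.out_dir`` is set, per-step populations, a text log and a TSV
    of (step, iteration, type, violations) are written there.
    """
    from .genome import segment_genome

    if segmentation is None:
        segmentation = segment_genome(config.chrom_sizes, config.bin_size, config.ploidy)
    geometry = NuclearGeometry(tuple(config.semiaxes))
    r0 = bead_radius_from_occupancy(geometry, segmentation.N, config.occupancy)
    beads = BeadGeometry(r0, config.occupancy)

    out_dir = None
    log_lines: list[str] = []
    tsv_rows: list[tuple] = []

    def log(step, it, thr, frac, violations):
        stamp = time.strftime("%H:%M:%S")
        line = (
            f"{stamp} step={step} iter={it} theta={thr.theta} lam={thr.lam} "
            f"tol={thr.tol} rho={thr.rho} violation_fraction={frac:.3e} "
            + " ".join(f"{k}={v}" for k, v in violations.items())
        )
        log_lines.append(line)
        if progress:
            print(line, flush=True)
        for kind, count in violations.items():
            tsv_rows.append((step, it, kind, count))

    if config.out_dir:
        import pathlib

        out_dir = pathlib.Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    engine = dict(config.engine)
    params = MinimizeParams(**engine) if engine else MinimizeParams()

    pop = initial
    if pop is None:
        pop = init_population(segmentation, geometry, beads, config.S, seed=config.seed)
    states: list[ConvergenceState] = []
    for k, thresholds in enumerate(config.threshold_steps()):
        pop, state = run_step(
            pop,
            bundle,
            thresholds,
            params=params,
            max_am_iter=config.max_am_iter,
            contact_range=config.contact_range,
            contact_scale=config.contact_scale,
            step_index=k,
            seed=config.seed,
            log=log,
        )
        states.append(state)
        if state.stalled:
            msg = f"step {k} stalled at violation fraction {state.history[-1]:.3e}"
            log_lines.append("WARNING " + msg)
            if config.strict:
                raise GenomePopError(msg)
        if out_dir is not None:
            write_population(pop, out_dir / f"population_step{k}.h5")
    if out_dir is not None:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        with open(out_dir / "violations.tsv", "w") as fh:
            fh.write("step\titeration\ttype\tviolations\n")
            for row in tsv_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        write_population(pop, out_dir / "population_final.h5")
    return pop, states
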