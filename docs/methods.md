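# Methods

## Genome and nucleus representation

Chromosomes are tiled with half-open, 0-based genomic bins of fixed size
(default 200 kb; the last bin of a chromosome may be short). Every bin of
every homolog copy is one spherical chromatin domain ("bead"); diploid beads
are stored as two contiguous haploid blocks (all copy-0 beads, then all
copy-1 beads), so population files are portable across tools that only need
the `(chrom, start, end, copy)` index. Copy numbers are per-chromosome
configuration (default 2); a haploid chromosome simply contributes no bead
to the copy-1 block.

The nucleus is a sphere or ellipsoid of semiaxes `a ≥ b ≥ c` (nm), centered
at the origin. The bead radius follows from the target genome volume
occupancy φ (default 0.40):

    r0 = (φ · abc / N)^(1/3),

so N beads occupy exactly φ of the nuclear volume. With the ellipsoid
(7,840; 6,470; 2,450) nm and N = 29,838 diploid beads this closed form gives
r0 = 118.55 nm; the commonly quoted 118 nm corresponds to a 39.45%
occupancy — the two statements are mutually inconsistent at the last digit,
and this package keeps the closed form.

Two radial quantities are used throughout. The semiaxis-normalized radial
position `r = sqrt((x/a)² + (y/b)² + (z/c)²)` is 0 at the center and 1 on
the envelope. The distance to the envelope uses the radial approximation
`d = (1/√κ − 1)·‖x‖` (exact for spheres); at the singular center point the
smallest semiaxis `c` is returned, a conservative lower bound that is only
reachable in degenerate tests.

## Data representation

* Hi-C: symmetric H×H contact probability matrix `A` (diagonal ignored).
* Lamina DamID: length-H contact probability vector `E`.
* Radial FISH: per locus, the sorted per-structure maximum and minimum
  radial positions over the homolog copies (`Z^max`, `Z^min`, length S
  each), in either normalized radial units or nm — declared in the file
  header, because the two conventions coexist in practice.
* Pairwise FISH: per locus pair, the sorted per-structure maximum and
  minimum over the CN(I)·CN(J) copy-pair distances (nm).
* SPRITE: one cluster per line, each a set of ≥ 2 haploid bins.

Probabilities may overshoot [0, 1] by at most 1e−9 (clipped); anything
larger is a hard error naming the offending row. The population container
is HDF5: `/coordinates` (float32, S×N×3 nm), `/radii`, `/index`, with the
semiaxes, bin size, seed, schedule step and a segmentation checksum as
attributes; reads validate the checksum so a population can never be paired
with the wrong binning.

## The A-step

All allocations are deterministic: stable sorts, ties broken by structure
index then copy-pair index (fixed `(copy_i, copy_j)` lexicographic order).

* **Contacts.** Every pair with `a_IJ ≥ θ` receives
  `k = max(1, round(a_IJ·S))` activations (round half away from zero; the
  floor of 1 ensures retained data are represented at least once; k is
  capped at S, bounding the effective simulated probability at 1). The k
  selected structures are those whose minimal copy-pair distance is
  currently smallest; within each, the argmin copy pair is activated.
* **Lamina.** Every bin with `e_I ≥ λ` activates `round(e_I·S·CN(I))`
  (structure, copy) candidates, ranked by largest radial position.
* **FISH.** The model's per-structure max (min) values are sorted and
  matched rank-to-rank against the sorted input `Z^max` (`Z^min`); each
  match restrains the bead (or copy pair) that realized the extremum in
  that structure, with a two-sided tolerance `t·target`. Rank-to-rank
  matching is the optimal 1-D transport plan, consistent with the
  Wasserstein-based assessment.
* **SPRITE.** The cluster radius is `r_c = (Σ_members r_i³ / ρ)^(1/3)`, the
  sphere that holds the summed member volumes at packing fraction ρ. For
  each structure, all copy combinations are enumerated (up to 10 members;
  greedy member-by-member selection beyond) and scored by the maximal
  member distance to the combination centroid; the cluster is assigned to
  the single best-scoring structure — a cluster is a single-cell
  observation, so exactly one structure hosts it.

## The M-step

Each activation becomes a distance restraint with a flat-bottom quadratic
penalty; uniform force constants per kind (default 1). Bounds:

| kind             | form                                                    |
|------------------|---------------------------------------------------------|
| envelope         | per bead, normalized radius ≤ 1 w.r.t. axes − r_i       |
| excluded volume  | d ≥ r_i + r_j (hard core)                               |
| bond             | consecutive beads of one copy chain, d ≤ 2(r_i + r_j)   |
| contact          | assigned pairs, d ≤ 2(r_i + r_j)                        |
| lamina           | bead outside the shell of axes (1 − c_r)·axes − r_i     |
| radial / pair    | two-sided, \|d − target\| ≤ tol                         |
| cluster          | members within r_c of the member centroid (dynamic)     |

Residuals are relative: `η = max(0, (d − b)/b)` for one-sided bounds (sign
flipped for lower bounds) and `η = max(0, (|d − target| − tol)/target)` for
two-sided targets; `η > 0.05` is a violation. Dimensionless (radial-norm)
measures are multiplied by the smallest semiaxis inside the energy so that
all penalties and gradients are in nm; the cluster centroid is recomputed at
every gradient evaluation, and its back-reaction term is included in the
gradient (verified against finite differences, as are all other kinds).

Structures are independent minimization problems. The engine evaluates the
whole population in one vectorized pass purely for speed; noise streams are
seeded per (run seed, structure index), so the joint result is bitwise
identical to optimizing each structure alone. The minimizer is gradient
descent with momentum (0.6) and a three-stage annealing schedule — noise
amplitudes `0.3·r0`, `0.075·r0`, then 0 over a 300-iteration budget — with
per-bead steps clipped at `0.5·r0`. In the noise-free stage a per-structure
backtracking rule (revert and halve the step size when a structure's energy
rises) makes the accepted-step energy non-increasing; structures whose
energy reaches zero are frozen. The excluded-volume sum is pruned with a
KD-tree neighbor list (cutoff `2·r_max` plus a one-radius skin, rebuilt
every 15 iterations); the residual report nevertheless counts all
N(N−1)/2 pairs per structure as restraints, since pruning is an evaluation
shortcut, not a change of the restraint set.

## Schedules and convergence

Thresholds move monotonically across steps — θ and λ down, FISH tolerance
down, SPRITE density up — so retained-data sets only grow and tolerances
only tighten. Defaults (all configurable):

    θ: 1.0, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002
    λ: 0.9, 0.6, 0.4, 0.2, 0.1, 0.05
    t: 1.0, 0.5, 0.2, 0.1, 0.05   (fraction of the target distance)
    ρ: 0.05, 0.1, 0.2, 0.4

Shorter schedules hold their final value once exhausted; final thresholds
must be positive (very low-probability entries are the most
noise-contaminated). A step's A/M loop (≤ 10 iterations by default) is
converged when the cumulative violation fraction — violations over all
restraints of all kinds — drops below 1e−4 (0.01%), the exact criterion
used for every convergence decision in the package; a stalled step logs a
warning and continues unless strict mode is on. Initialization samples each
chromosome copy uniformly inside a territory sphere of radius
`r0·n^(1/3)·packing` (packing 1.4 ⇒ 36% internal occupancy), itself placed
uniformly so it fits inside the nucleus, followed by a short geometry-only
relaxation.

## Structural observables

Contact simulation declares beads in contact at `d ≤ 2(r_i + r_j)` and
averages copy pairs with the `min(CN(I), CN(J))` normalization, clipping at
1 (both homolog pairs in contact everywhere would otherwise give 2). The
DamID simulation tests beads against the shell ellipsoid with axes
`(1−c_r)·(a, b, c) − r_i` (boundary inclusive). A published variant of this
formula scales the z-term by semiaxis `b` rather than `c`; we read that as a
typo and use `c`, but the variant is switchable (`z_semiaxis="b"`).

Speckle locations are predicted per structure by Markov clustering (MCL,
inflation 1.5, expansion 2, pruning 1e−5 — parameters are rarely published;
these are standard values and configurable) of the graph on the beads of the
5% of bins with the lowest population-mean radial position, with edges at
`d ≤ 4·r0`; cluster centroids are the bodies (singletons allowed). Lamina
domains use the same pipeline on the top-15% radial beads selected per
structure. TSA-seq-like signals are `sig_i = (1/S)·Σ_s Σ_l exp(−R0·d)` with
distances in µm and decay R0 = 4 per µm — with d in nm the exponential
would vanish, so the per-µm reading of the published constant is adopted —
normalized as `log(sig/mean sig)`; copies are averaged before
normalization, which makes the genome mean of `exp(track)` exactly 1.

SAF counts (structure, copy) observations within 1,000 nm of the nearest
body centroid (centroid rather than body surface; 500 nm is the threshold
used against imaging data); LAF counts radial positions above 0.85. The
trans A/B ratio uses `n_A/(n_B + 1)` over trans neighbors within 500 nm
(pseudocount in the denominator only, matching the worked arithmetic of the
definition we follow), takes the median over copies and structures, skips
empty neighborhoods, masks bins with none, and min–max rescales to [0, 1].
The per-structure compartmentalization score is implemented exactly as
printed, `log2(2·P(A)·P(B)·T/N_AB)` with `P(A) = (2N_AA + N_AB)/T` — note
P(A) + P(B) = 2 under this normalization; a `/2T` variant is available
behind a flag. N_AB = 0 masks the structure. Cell-to-cell variability is
`δ_I = log2(σ_I/σ̄_c)` with σ pooled over copies; σ below 1e−12 (identical
positions, numerically) is masked.

## Synthetic ground truth and assessment

The generator emulates the salient organization of interphase nuclei rather
than any particular dataset: each chromosome copy is grown as a random walk
(steps uniform in [2, 4]·r0, matching the bond bound) confined to a
territory sphere (packing 1.4, like the initializer) and to the envelope,
with a label-dependent radial acceptance — B-labeled beads accept a
candidate at radial position r with probability `sigmoid(bias·(r − 0.5))`,
A-labeled beads with the mirrored probability — followed by a geometry-only
clash relaxation. A/B labels are blocky (smoothed noise thresholded at the
A fraction) and can be held fixed across replicate seeds (`label_seed`).
What the generator does **not** emulate: experimental noise and coverage
bias, cell-cycle and cell-type heterogeneity, sub-bin chromatin structure,
irregular or variable nuclear shapes, and the ~100-fold cis/trans contact
ratio of real genomes — at desk scale (a few hundred beads at 40%
occupancy) the chance-contact floor is ~0.1 per pair, so trans contact
probabilities are far denser than in real data. Passing tests therefore
demonstrate the self-consistency of the deconvolution, not instrument-level
realism.

Assessment statistics: 1-D Wasserstein distances on pooled samples (the
max and min distributions of a target concatenated); the cross-Wasserstein
score is the Pearson correlation between two populations' vectors of all
within-population pairwise Wasserstein distances over a common target set.
The stratum-adjusted correlation pools matrix diagonals across chromosomes
up to 50 Mb and weights each stratum's Pearson r by `N_k·sqrt(var₁·var₂)`
(h = 0: no smoothing). The χ² goodness-of-fit test bins the pooled sample
by the Sturges rule, merges bins to an expected count of ≥ 5, and rejects
outright when the model occupies a category impossible under the reference
(this handles the binary SPRITE-presence variant, whose reference is all
ones). The overall performance rank is `OPR_s = Σ_f (n_setups + 1 −
rank_f^s)`; with 8 setups and 7 features the range is 7 (uniformly last;
the figure-legend claim of 8 disagrees with its own formula) to 56.
Imaged-structure matching drops structures below 80% locus coverage or
fewer than 10 assigned regions, linearly interpolates remaining gaps, and
matches by Pearson correlation of min–max-normalized flattened distance
matrices (normalization removes uniform scale).

## Benchmark problem sizes and expected headline numbers

The two built-in benchmarks are sized for a single CPU: the recapitulation
run uses 2 chromosomes × 60 bins (N = 240, S = 100) with Hi-C, DamID and 51
pairwise FISH distributions as inputs; the perturbation run uses 3 × 50
bins modeled from intra-halved Hi-C alone. Both finish in a few minutes.
At this scale the pipeline converges (violation fraction < 1e−4 at every
step) and recapitulates Hi-C at r ≈ 0.96–0.97 over retained entries, DamID
at r ≈ 0.95–0.97, and the FISH cross-Wasserstein score at ≈ 0.98–1.0.
Hi-C recapitulation is bounded away from 1 at this scale by the
chance-contact floor: restraints are one-sided (there is no anti-contact
restraint kind, by design), so entries whose probability is below the
incidental-contact rate cannot be bound from above, and their sampling
noise decorrelates the low-probability block. For the same reason —
compounded by the intrinsic noise of predicted-body TSA tracks when only
~8 bins are speckle-selected — the perturbation run's track correlations
sit far below their full-genome counterparts; an independent replicate of
the ground truth itself scores only ≈ 0.45 (TSA) to ≈ 0.92 (DamID) against
the truth at this scale, which is the ceiling any model could reach.

## Known limitations

Restraints are positive-only (enforce presence, never absence), so
simulated contact frequencies are inflated toward the chance floor at high
crowding. The ellipsoid-distance formula is a radial approximation. The
SPRITE copy-combination search is exhaustive only up to 10 members. The
engine is single-process; population sizes beyond a few hundred structures
× a few thousand beads call for the cluster-scale implementations this
package deliberately does not replicate.
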