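# genomepop

Population-based integrative modeling of 3D genome organization.

Ensemble genomics assays describe nuclear architecture only as averages over
millions of cells: Hi-C gives the probability `a_IJ` that two genomic loci
touch, lamin B1 DamID the probability `e_I` that a locus contacts the nuclear
lamina, and high-throughput 3D FISH the distributions of radial positions and
pairwise distances of selected loci. None of these reveal *which* cell holds
*which* contact, nor which homologous copy is involved. `genomepop`
deconvolves such data — optionally together with single-cell SPRITE
colocalization clusters — into a **population of S diploid 3D genome
structures** `X = {X_1, …, X_S}` that jointly reproduce all of the input
statistics, and then computes a suite of structural features (speckle- and
lamina-proximity signals, association frequencies, compartmentalization
scores, radial profiles, …) from the resulting single-cell models. It is
aimed at computational genome-architecture researchers who want a desk-scale,
fully scriptable implementation of this class of model, including a synthetic
ground-truth harness for benchmarking data-integration strategies.

## The model

Each chromosome is segmented into fixed-size bins (default 200 kb); every bin
of every homolog copy is a spherical chromatin domain of excluded-volume
radius `r0`, chosen so the diploid genome occupies 40% of the nuclear volume
(an ellipsoid of semiaxes `a ≥ b ≥ c`). Estimation is a **latent-variable
hard-EM** scheme: binary indicator tensors `W, V, B, F, R` expand the
ensemble data `A, E, U, M, T` to single-structure, single-copy resolution,

* **A-step** — given the current population, each retained observation is
  allocated where it is cheapest: a Hi-C entry `a_IJ ≥ θ` activates
  `k = max(1, round(a_IJ·S))` contacts in the k structures whose closest copy
  pair is shortest; a DamID entry `e_I ≥ λ` activates the
  `round(e_I·S·CN(I))` outermost (structure, copy) candidates; FISH max/min
  distance distributions are rank-matched to the model's max/min
  distributions; each SPRITE cluster is hosted by the structure with the most
  compact copy combination.
* **M-step** — the activations become flat-bottom quadratic distance
  restraints (contact: `d ≤ 2(r_i+r_j)`; lamina: bead outside the shell
  ellipsoid; FISH: two-sided `|d − target| ≤ t·target`; cluster: members
  within the density radius `r_c`), joined by the always-on envelope,
  excluded-volume and chain-connectivity restraints, and every structure is
  relaxed independently by annealed gradient descent.

Steps alternate under a schedule of loosening thresholds (θ, λ decreasing;
FISH tolerance t decreasing; SPRITE density ρ increasing), and an A/M round
converges when fewer than 0.01% of all restraints deviate more than 5% from
their bound (the residual `η`).

## Worked example

Build a synthetic "true" population, simulate Hi-C + DamID + FISH from it,
and deconvolve them back:

```python
import numpy as np
from scipy import stats
import genomepop as gp

# 1. a synthetic "true" population: 2 diploid chromosomes x 30 bins, S = 50
spec = gp.GroundTruthSpec(
    chrom_sizes={"chrA": 6_000_000, "chrB": 6_000_000},
    S=50, semiaxes=(2000.0, 1700.0, 1400.0), radial_bias=4.0, seed=1,
)
truth = gp.generate_ground_truth(spec)
print(f"ground truth: S={truth.S}, N={truth.N} beads, r0={truth.radii[0]:.0f} nm")

# 2. synthesize Hi-C, DamID and 10 pairwise FISH distributions from it
bundle = gp.simulate_inputs(truth, n_radial=0, n_pairs=10, seed=1)
bundle.fish_radial = None

# 3. deconvolve them back into a population of 50 structures
cfg = gp.RunConfig(chrom_sizes=spec.chrom_sizes, semiaxes=spec.semiaxes, S=50, seed=2)
model, states = gp.run_pipeline(cfg, bundle)
print(f"converged: {all(s.converged for s in states)}, "
      f"final violation fraction: {states[-1].history[-1]:.1e}")

# 4. the model statistically reproduces its inputs
A_in, A_out = bundle.hic.matrix, gp.simulate_contact_matrix(model).matrix
mask = np.triu(A_in, 1) >= 0.002
print(f"Hi-C recapitulation r = {stats.pearsonr(A_in[mask], A_out[mask])[0]:.3f}")
e_out = gp.simulate_damid_profile(model).values
print(f"DamID recapitulation r = {stats.pearsonr(bundle.damid.values, e_out)[0]:.3f}")
```

Output (about 20 s on one CPU):

```
ground truth: S=50, N=120 beads, r0=251 nm
converged: True, final violation fraction: 0.0e+00
Hi-C recapitulation r = 0.933
DamID recapitulation r = 0.924
```

The recapitulation correlations say that contact and lamina-contact
frequencies recomputed from the optimized single-cell structures match the
ensemble inputs; they rise with the genome and population size (≈0.97 at the
benchmark scale below). Feature tracks (`basic_tracks`, `tsa_signal`,
`association_frequencies`, `compartment_score`, …) are then computed from
`model`.

A CLI mirrors the library for shell use: `genomepop simulate` (ground truth
and input files), `genomepop run --config cfg.json` (the optimization),
`genomepop features` (the track suite) and `genomepop assess` (scoring model
populations against a ground truth).

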