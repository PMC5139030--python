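# Methods

This note documents the models, algorithms, defaults and design choices in
`modelqa`, in enough detail to judge what the package computes and what its
synthetic benchmarks do and do not demonstrate.

## Problem setting

A single-model quality-assessment method maps one candidate protein
structure to an estimate of its GDT-TS similarity to the native structure,
without reference to other candidates. The package implements the full
loop: feature extraction from a model, a trainable regressor, structure
similarity scores for ground truth, and the evaluation statistics used to
compare QA methods across targets.

## Structural model representation

A `ProteinModel` is an ordered list of residues, each with a map of atom
coordinates. Parsing (Biopython's PDB parser underneath) takes the first
chain of the first MODEL block, resolves altlocs to the highest-occupancy
conformer, skips heteroatoms, and rejects any residue without a CA atom —
so per-residue feature vectors always have length L. Models whose length
differs from the target sequence are rejected rather than aligned; the
intended inputs are full-length decoys of a single-domain target.

## Geometry primitives

**Superposition.** Kabsch's SVD solution with the determinant correction to
exclude reflections. Used for RMSD and inside the GDT/TM searches.

**SASA.** Shrake–Rupley with deterministic Fibonacci-sphere sampling
(default 92 points, probe 1.4 Å; radii C 1.70, N 1.55, O 1.52, S 1.80 Å).
Sampling directions are fixed, which would make results depend on the
molecule's orientation in the lab frame; coordinates are therefore first
expressed in a canonical frame (principal axes, signs fixed by the third
moment of the projections) so SASA is invariant under rigid-body motions to
machine precision. Relative accessibility divides by a per-residue
theoretical maximum (Tien et al. 2013 values); residues at or above 0.25
relative accessibility are "exposed" (a common 2-state convention;
configurable in code). CA-only models fall back to a 2.0 Å pseudo-atom per
residue and are flagged as approximate — their absolute areas are
meaningful relatively, not against the reference maxima.

**Secondary structure.** A deterministic dihedral-window assigner: H for
runs of ≥4 residues with φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); E for runs of
≥2 with φ ∈ (−170°, −50°), ψ ∈ (80°, 180°) ∪ (−180°, −170°); C otherwise,
including chain termini where a dihedral is undefined. This is a geometric
stand-in for a hydrogen-bond-based assigner (DSSP); wherever an SS string
is consumed a precomputed DSSP string may be supplied instead, reduced
8→3 by {H,G,I}→H, {E,B}→E, else C.

## Features

All 16 features live in [0, 1]; missing inputs are imputed at 0.5, and
imputation is never fatal. Orientation is uniform: higher = more
native-like.

| key | definition |
| --- | --- |
| SU | exposed-nonpolar SASA / total SASA; nonpolar set {A,V,L,I,P,F,M,W,G,C} |
| EM | mass of exposed residues / total mass (average residue-mass table, Da) |
| ES | total SASA / Σ per-residue reference maxima, clamped |
| SA | fraction of residues whose exposed/buried state matches the 2-state prediction |
| SS | Q3 agreement between model SS and the 3-state prediction |
| SP | agreement restricted to positions predicted H or E; 0.5 if none predicted |
| EC | mean pairwise CA distance / (3.8 · (L−1)), clamped |
| DFIRE2, RWPLUS, RF_CB_SRS_OD | raw energies via the fixed linear maps in the README, clamped |
| DOPE, GOAP, OPUS | −P/(c·L) with calibration constants c = 2.0, 20.0, 2.0 (no published map exists for these; the constants are exposed knobs chosen so typical decoy energies land mid-range) |
| PROQ2, MODELEVALUATOR, QPROB | already unit-interval scores, clamped pass-through |

Interpretation choices worth flagging: SP is defined as a match fraction
(higher = better) so that all features share orientation, even though
"penalty" suggests the opposite sign; EC's denominator is read as the
maximum possible extended-chain span 3.8·(L−1) Å; SA and SS use match
fractions rather than 1 − normalized difference (the two are equivalent up
to ordering). The reduced 9-feature set (`deepqa9`) is
SU, DOPE, GOAP, OPUS, RWPLUS, MODELEVALUATOR, SP, EC, QPROB.

## Deep belief network

Architecture: input (16 or 9) → RBM1 (N1 = 20 hidden) → RBM2 (N2 = 10
hidden) → one logistic output node; sigmoids everywhere, so predictions are
strictly inside (0, 1).

**Pretraining.** Layer-wise CD-1. Visible units are treated as real-valued
probabilities in [0, 1] (the features are normalized scores); hidden states
are Bernoulli-sampled in the positive phase, and the reconstruction uses
probabilities. The second RBM trains on the first RBM's hidden
*probabilities*. Update rule per minibatch:
velocity ← ν·velocity + ε·(⟨v h⟩_data − ⟨v h⟩_recon − ω·W), W ← W + velocity,
with ε = 1e-4, ω = 0.007 (weights only), momentum ν = 0.5 for the first 5
epochs then 0.9, batch size 100, 100 epochs, initial weights N(0, 0.01²).
Epoch/batch counts and the CD-1 choice are package defaults, exposed in
`TrainConfig`.

**Fine-tuning.** The stack plus output node is treated as a plain
feed-forward sigmoid network; full-batch mean squared error is minimized by
BFGS (SciPy) with analytic backpropagated gradients (verified against
central finite differences in the tests). The line search guarantees the
objective never increases between accepted iterates; stopping is gradient
tolerance 1e-8 or 500 iterations. With ε = 1e-4 the pretraining nudges
weights only slightly from their random initialization — the heavy lifting
is done by BFGS, and pretraining's role is a structured initialization.

**Cross-validation.** Seeded shuffle into 5 folds (sizes within one of each
other); per-fold MAE of the held-out predictions plus the mean. The whole
training pipeline is deterministic given the seed, to the bit.

Models serialize to JSON (weights, config, feature set, metadata);
round-trips predict identically.

## Structure similarity scores

**GDT-TS** averages, over cutoffs {1, 2, 4, 8} Å, the largest fraction of
CA atoms that can be superposed within the cutoff. The search is an
LGA-style heuristic: seeds are the full chain plus 3-residue fragments
(every contiguous window for L > 12; for L ≤ 12 every 3-residue
combination, which makes the search near-exhaustive on toy chains); each
seed superposition is refined both by progressive extension (superpose on
the n best-fitting residues, n growing one at a time) and by cutoff-driven
fixed-point iteration (keep residues within d, re-superpose). The reported
score maximizes over all candidate superpositions, and is a lower bound on
the exhaustive optimum; on random L ≤ 10 decoys it sits within 0.05 of a
brute-force all-subsets oracle (tested).

**TM-score** maximizes (1/L) Σ 1/(1+(d_i/d0)²) over the same candidate set
(with d0 added to the cutoff list), d0 = 1.24·(L−15)^⅓ − 1.8 floored at
0.5 Å so short synthetic chains remain scoreable. **RMSD** is plain CA
RMSD after superposition on all residues.

**Evaluation statistics.** Per-target Pearson r (targets with degenerate
pools — fewer than 3 scored models or zero variance — are excluded from
averages); per-target loss max(true) − true(top-ranked), ties on the
predicted score broken by model id; best-of-top-k TM-score and RMSD;
Z-score sums standardized by the pool's population standard deviation
(degenerate pools contribute 0); two-sided Wilcoxon signed-rank with zero
differences dropped and mid-ranks for ties — exact by enumeration of all
2^n sign assignments for n ≤ 12, normal approximation with continuity and
tie corrections otherwise (all-zero differences are flagged degenerate,
p = 1). Local per-residue error estimates convert to a global score by
(1/L) Σ 1/(1+(ℓ_i/5)²).

## Synthetic data

`generate_native` grows an ideal backbone (N, CA, C; standard bond lengths
and angles, trans peptides) from template dihedrals: helix (−57°, −47°),
strand (−120°, 120°), coil (65°, 35°, outside both assignment windows), or
mixed segments with coil linkers. `generate_decoys` adds i.i.d. Gaussian
coordinate noise per atom followed by a random rigid re-orientation; the
default σ grid {0.5, 1, 2, 4, 8} Å spans GDT-TS ≈ 1 down to ≈ 0.2, giving a
monotone ground-truth ordering. Gaussian perturbation was chosen over
fragment re-assembly for analytic transparency.

External tool scores are emulated by pushing a noisy copy of the decoy's
true GDT-TS (sd 0.05) through the inverse of each normalization map, so the
synthetic pools carry the same feature→quality structure that real energy
scores do. SS/SA "predictions" are derived from the native, emulating a
sequence-based predictor that is accurate about the native state.

`generate_feature_dataset` draws features uniformly on [0, 1] and sets the
target to a sigmoid of the sum of two designated informative features plus
Gaussian noise (sd 0.05 by default), clamped to [0.01, 0.99] to avoid
output-sigmoid saturation; the generating function is returned for oracle
checks.

**What the synthetic benchmarks show — and don't.** Passing them shows the
machinery is correct: features are well-defined and bounded, the learner
recovers a known monotone mapping (held-out r ≈ 0.99, MAE ≈ 0.04 at
n = 2000), and the end-to-end pipeline ranks unseen noise-graded pools
almost perfectly. They do not show performance on real decoys: Gaussian
noise is an easy, radially symmetric corruption, the emulated external
scores are honest noisy oracles of the truth, and real CASP-style pools
have systematic, correlated errors. Numbers from the synthetic conditions
are upper bounds on realism, not estimates of blind-test accuracy.

## Problem sizes and numerical choices

The shipped benchmarks use n = 2000 for the feature dataset and pools of
100 decoys at L = 30 (training and evaluation pools from different natives)
— large enough for stable statistics while keeping a full run in minutes on
one CPU. Tolerances: GDT heuristic vs brute force 0.05; SASA at 92 points
vs 960 points 3%; gradient check relative error 1e-5; rigid-invariance
checks 1e-9. Degenerate inputs are handled explicitly: empty pools and
length mismatches raise; missing features impute; zero-variance pools drop
out of correlation averages and contribute zero to Z-sums; sigmoid inputs
are clipped at ±500 to avoid overflow.

## Known limitations

* The SS assigner is geometric, not hydrogen-bond based; on real structures
  it will disagree with DSSP near helix termini and in distorted strands.
* GDT-TS/TM-score use a heuristic search, not the LGA program; scores are
  lower bounds and can differ slightly from published tools.
* CA-only SASA is a coarse pseudo-atom approximation.
* The Dope/GOAP/OPUS normalization constants are calibration knobs, not
  published values; with real tool outputs they should be fitted once on a
  training set.
* No residue-level quality prediction; only the local→global conversion
  formula is provided.
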