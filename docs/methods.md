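# Methods

This note documents the models, protocols, numerical choices, and known
limitations of `molfoundry`, in the spirit of a methods appendix.

## Molecular representation

Molecules are heavy-atom graphs. Hydrogens are folded into a per-atom H-count
feature rather than carried as nodes: explicit-H graphs would roughly double
the node count and triple the geometry-target volume without adding
information a 2D model can exploit. Atom features are a one-hot element over
a configurable vocabulary (default: C, N, O, F, P, S, Cl, Br, I, B, Si),
formal charge, heavy-atom degree, aromaticity flag, H-count, and a 3-slot
one-hot tetrahedral chiral tag (none / clockwise / counterclockwise). The
chiral tag lives at the atom level so the message function can see it; it is
the only feature distinguishing enantiomers, which is exactly the intended
behavior: with chirality encoding disabled, enantiomer pairs are
indistinguishable by construction (asserted bitwise in the tests). The exact
feature set is a design choice of this package; element, charge, degree,
aromaticity, H-count and chirality are the conventional minimal set.

Atoms are renumbered at parse time by a chirality-agnostic canonical ranking,
so serialization is stable and enantiomers share an ordering. No model output
may depend on atom order; permutation equivariance of atom states and
invariance of the latent are fuzz-tested.

File formats: SMILES via RDKit; SDF (V2000/V3000) via RDKit's supplier with
per-record reject reporting; small-molecule CIF via gemmi with bond
perception from coordinates (records whose perception fails are rejected as
"ambiguous bonding"). Note that reading 3D records perceives stereocenters
from coordinates, so a graph written without chiral annotations can come back
with them; connectivity always round-trips.

## Geometry targets

For each atom: Euclidean distances to its bonded neighbors (canonical index
order, default cap 4 — standard organic valences) and the angle at the atom
for every pair of kept neighbors (cap 6 = C(4,2)), padded and masked.
"Neighbors" default to bonded atoms, which makes the angles bond angles; a
`spatial_knn` mode is available where nearest is taken literally. Angles are
stored in degrees and computed with the atan2 form
`atan2(|u×v|, u·v)`, which stays well-conditioned for collinear neighbors
(sp centers) where arccos loses ~7 digits; measured invariance error under
random rigid motions is ~1e-13. Distances and unsigned angles are also
reflection-invariant, so the targets cannot distinguish enantiomers — chiral
information enters only through the atom features. Coinciding atom positions
raise an error naming the pair.

## Backbone

The MPNN embeds atom features, runs `message_steps` rounds in which each atom
receives the sum of its neighbors' states transformed by a weight matrix
selected by the connecting bond's order (single/double/triple/aromatic) —
the simplest faithful edge conditioning — and applies a shared self-update
with ReLU. Weights are shared across rounds. Defaults: hidden 128, 3 message
steps, readout (latent) width 256, sum aggregation; these are package
defaults chosen to be comfortably CPU-trainable, all config-exposed. Tests
and the acceptance script use a 32/2/32 configuration for speed; the methods
are size-agnostic.

The latent is the post-pooling penultimate activation:
`z = ReLU(W_read · pool(h) + b_read)`. The same `W_read` is also applied
per-atom to feed the geometry output heads during pretraining (weight tying).
This is a deliberate design choice: it puts the readout weights on the
pretraining gradient path, so the latent transform is itself trained rather
than remaining a random projection. Geometry heads are linear maps from the
per-atom readout activation to the padded distance vector (Å) and to angles
on a [0, 1] scale (reported ×180 in degrees).

Everything is NumPy float64 with hand-written backpropagation and Adam
(β₁ 0.9, β₂ 0.999). Gradients are verified against central finite differences
to ~1e-5 relative error (the residual is the L1/ReLU kink set). Parameters
carry a SHA-256 content fingerprint over config and sorted tensors; the
checkpoint loader verifies it, and the freeze contract is expressed as
fingerprint equality.

## Pretraining

Loss = masked mean |Δdistance| (Å) + `angle_weight` × masked mean
|Δangle|/180, with means over all masked-in entries of the batch. L1 matches
the MAE evaluation criterion; the /180 normalization makes the two terms
commensurate and `angle_weight` defaults to 1. Optimizer Adam, default rate
1e-3 (5e-3 in the small fixture runs), molecule-count batches, optional early
stopping on a held-out scaffold split with configurable patience. Training is
deterministic given the seed. A non-finite loss aborts with a diagnostic.

## Transfer heads

`strip_and_attach` discards the geometry heads and initializes a 2-layer head
(He-scaled weights, zero biases) on the latent; only the head receives
gradients. Head input features are standardized with training-set statistics
(a fixed affine map of frozen features, stored with the head — not a backbone
modification). The per-dimension scale is floored at 1e-3 of the largest
feature standard deviation: a latent dimension that is constant across
training inputs but not on out-of-distribution inputs would otherwise explode
after division by a ~1e-8 standard deviation; this was observed on unseen
reaction components. Regression targets are likewise standardized internally
and un-standardized at prediction (L1 training moves outputs at a rate set by
the learning rate, so O(50) yield offsets would otherwise take thousands of
steps to traverse).

Regression trains on absolute error; multilabel trains independent per-class
binary cross-entropies ("multilabel multiclass"). Reaction inputs are the
concatenation of component latents in a fixed role order with zero blocks for
absent roles — concatenation (rather than pooling) preserves role identity,
which is what allows unseen-ligand and unseen-base splits to behave
differently. Yield predictions are clipped to [0, 100] at inference only.
Head presets: toxicity 256→124→1 (31,993 params), odor 256→86→113 (31,933),
yield base 1792→145→1 (260,131), yield large 1792→557→1 (999,259) — within
0.3% of the ~32k/~260k/~1M budgets; the exact widths behind those published
budgets are not stated anywhere, so the presets target the counts.
Multi-seed results are reported as mean ± standard error (sample std/√n).

## Curation and splits

* Rare elements: a molecule is dropped iff it contains an element with fewer
  than `min_count` (default 100) per-atom occurrences across the dataset,
  counted before any dropping — hence idempotent.
* Polymorphs: records sharing a canonical graph are compared pairwise by
  best-fit heavy-atom RMSD (Kabsch, proper rotations only); if any pair
  exceeds the threshold (default 1.0 Å — "significantly different
  conformations" is not quantified anywhere, so the threshold is exposed) the
  whole group is dropped. Correspondence uses canonical atom order, which can
  overestimate RMSD for molecules with symmetric automorphisms; acceptable
  for a filter whose failure mode is dropping a borderline group.
* Ambiguous bonding is operationalized as a parser/bond-perception failure
  flag, since curated ambiguity annotations are not available.
* Scaffold split: Bemis–Murcko frameworks, whole groups assigned greedily to
  the training side largest-first (ties shuffled by seed) until the train
  fraction is reached; remaining groups form the test set, so the realized
  fraction is correct to within one group and no scaffold straddles the
  split. Single-scaffold datasets are refused.
* k-fold unseen: canonical-structure duplicates are co-assigned; groups go to
  the currently smallest fold, largest first.
* Leave-component-out: one plan per held-out component; every test reaction
  contains it and no training reaction does, enforced by an audit that is run
  before any scoring. A `top_component_splits` helper holds out the
  most-frequent reactants for historical-data protocols; how many top
  reactants to hold out is config-driven (the reference protocol reports only
  that test sets were ~10% of training size).

## Synthetic fixtures

The generator emulates the *shape* of the real corpora, not their chemistry:

* Molecules: random valence-respecting trees over a C-weighted palette with
  occasional double bonds and one ring closure, sanitized, embedded once with
  ETKDG distance geometry and relaxed with MMFF (UFF fallback). This yields
  single-molecule gas-phase-like geometries — a documented surrogate for
  crystal conformations; no packing, no polymorphism, no disorder.
* Regression labels: linear in simple graph descriptors (atom/ring/heteroatom
  counts) or in a chosen frozen backbone's latent (standardized basis so
  labels have O(1) spread), plus Gaussian noise; coefficients, basis scaling
  and noise draws are stored, so recovery experiments have exact ground
  truth.
* Multilabel labels: stored structural rules (ring presence, specific
  elements, size, unsaturation, H-count thresholds) per class, plus a forced
  minority of all-zero rows mimicking label-free molecules.
* Reactions: factorial tables over role palettes; yield = clip(base + Σ_role
  a·atoms + b·heteroatoms, 0, 100) with optional noise and a configurable
  zero-yield "negative reaction" fraction.

Everything is reproducible from (config, seed). Passing tests on these
fixtures demonstrates the mechanics (invariance, freezing, split hygiene,
recoverability of known signal); it does **not** demonstrate chemical
accuracy on real toxicity, yield, or odor data, which would require the
external corpora.

## Problem sizes and numerical notes

The shipped experiments use 20–50 molecules for pretraining (300/150 epochs,
rate 5e-3), 500 molecules for latent-signal recovery (600 head epochs, rate
3e-3), a 192-reaction factorial table (8 electrophiles × 4 bases × 6 ligands)
for the unseen-ligand study, and 100 molecules × 8 classes for the multilabel
study — sizes chosen so the full pipeline runs in minutes on one CPU. Two
observations worth recording: pretraining a small backbone to convergence on
only ~20 molecules collapses much of the latent (many permanently inactive
units), which degrades downstream transfer — the transfer experiments
therefore pretrain on the full 50-molecule set; and with too few components
per reaction role (2–3 ligands) the component-effect mapping is
underdetermined and unseen-component extrapolation can underperform a mean
baseline, so the fixture uses 6 ligands. Ties in top-k label prediction break
toward the lower label index (stable sort). Zero-support classes contribute
F1 = 0 to the macro average and weight 0 to the weighted average. The
decision threshold for converting probabilities to labels is 0.5,
config-exposed; whether the reference protocol thresholds or uses top-k is
unstated.

## Limitations

* No tautomer/protonation standardization, no 2D depiction, no polymer or
  disorder handling in CIF.
* No torsions/dihedrals or intermolecular distances in the targets; no
  unit-cell handling.
* The backbone is a plain bond-conditioned MPNN: no attention, no 3D-input
  networks, no uncertainty estimation; heads never unfreeze the backbone.
* Published benchmark numbers for the real toxicity / yield / odor corpora
  are out of reach at fixture scale and are not claimed.
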