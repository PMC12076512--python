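# Methods

## The model

`profis` learns the inverse mapping from a binary molecular fingerprint to
a sequential notation of the molecule, then uses the learned embedding
space as the substrate for activity-guided compound generation.

**Stochastic encoder.** A fingerprint x̄ ∈ {0,1}ᵈ passes through two
fully-connected ReLU layers (reference width 1024, 1024) into two parallel
affine heads of width 32 producing μ(x̄) and log σ²(x̄). A latent sample is
drawn by the reparametrization z = μ + σ ⊙ ε, ε ~ N(0, I), keeping the
encoder differentiable. At inference the deterministic mean path (z = μ)
is used unless stochastic embeddings are requested explicitly.

**Decoder.** A stack of three GRU layers (reference hidden width 512)
generates the token sequence autoregressively. All hidden states start at
zero. At each step the GRU input is the concatenation of ω(z) — a single
affine layer mapping the latent vector to the decoder input space — and a
learned embedding of the previous token (a start marker at the first
step). An affine layer ψ with softmax maps the top GRU output to token
probabilities. Greedy decoding takes the argmax; sampled decoding draws
with a temperature. Generation stops at the end marker or at the fixed
sequence length k = 100.

Because the decoder is autoregressive it could in principle ignore z
entirely (the KL-vanishing failure); the wiring above — z injected at
*every* timestep through ω(z), zero hidden initialization — was chosen so
the latent code remains the only route by which molecule identity enters
generation.

**Loss.** L = CE + β_t · KLD, where CE is cross-entropy on the token
logits averaged over non-pad positions (masking was chosen so sequence
length does not distort the loss), and KLD = ½ Σ(μ² + σ² − log σ² − 1) is
the closed-form divergence from the standard-normal prior, averaged over
the batch. β = 0.1 in the reference configuration. β_t follows a cosine
annealing schedule over the first 50 epochs:
β_t = β · ½(1 − cos(π·epoch/50)), constant β afterwards — a monotone
half-cosine ramp, the specific functional form being a design choice
within "cosine annealing". Training uses Adam (lr 10⁻³ reference, 3·10⁻³
in the toy configuration), gradient-norm clipping at 5, teacher forcing
with the target sequence shifted by one, and is fully seeded: identical
seeds give bitwise-identical loss logs.

The network is implemented directly in NumPy (float64) with hand-written
backpropagation through time; gradient correctness is asserted against
central finite differences in the test suite. This keeps the package free
of deep-learning framework dependencies and makes every computation
deterministic under a seed.

**Scaled-down configuration.** `toy_config()` is the single source of
truth for test/demo scale: encoder (256, 256), three GRU layers of width
128, embedding 32, ω output 32, latent kept at the reference 32, batch 50.
Its KLD weight is β = 0.001 rather than 0.1: the per-molecule information
the latent must carry grows as the corpus shrinks (identifying one of ~10²
molecules needs a latent budget that β = 0.1 — balanced for a ~10⁶
corpus — suppresses entirely, producing exactly the posterior collapse the
annealing schedule is meant to fight). With β = 0.001 a 50-molecule corpus
is memorized to ~100% exact greedy reconstruction within 200 epochs
(~30 s on one CPU); the annealing schedule itself is unchanged.

## Data preparation

Standardization keeps the largest organic fragment (ties broken by
lexicographically smallest canonical SMILES), neutralizes charges with
RDKit's Uncharger, strips all stereochemistry, and canonicalizes; the
operation is a fixed point on its own output. Training-set filters demand
molecular weight 200–450 g/mol and zero violations of the four classic
rule-of-five criteria (MW ≤ 500, clogP ≤ 5, HBD ≤ 5, HBA ≤ 10 — the
package interprets "no violations" as all four satisfied).

The train/test split is scaffold-grouped: molecules are grouped by
Bemis–Murcko framework (all acyclic molecules share one "empty scaffold"
group, preventing leakage of the no-ring class), groups are drawn in
seeded random order, and a group joins the training set only if the
result stays within the training fraction (the check is prospective, so
the cap is never exceeded); otherwise the whole group goes to the test
set.

## Fingerprints

ECFP4 is the radius-2 Morgan fingerprint folded to a configurable width
(default 2048; the encoder input adapts). The Klekota–Roth-dimensional
fingerprint has exactly 4860 substructure keys, bit i set iff key i occurs
in the molecule. The published Klekota–Roth SMARTS inventory is not
shipped; instead `krfp_synthetic.py` enumerates a deterministic synthetic
key set of the same size and semantics (single atoms with explicit H
states, bonded pairs, short chains and branched centers over common
organic elements), with a SHA-256 provenance hash of the inventory. All
dimensional and matching contracts are identical to the real key set;
individual bit meanings are not.

Tanimoto distance is 1 − |a∧b|/|a∨b|; the all-zero/all-zero pair is
defined to have distance 0 so identity of indiscernibles holds
degenerately but deterministically. Bit-flip noising flips exactly k
positions drawn uniformly without replacement under a seed.

## Notations

Three sequential notations are implemented in-package and selected per
model:

* **SMILES** — canonical, stereo-free; tokenized by greedy longest match
  (bracket atoms, Cl/Br and ring-closure escapes are atomic tokens).
* **DeepSMILES** — matched ring-closure digits are replaced by a single
  ring-size symbol at the closing atom, and branches lose their opening
  parenthesis (one `)` per branch atom). Decoding maintains a stack of
  atoms on the current path; a ring symbol n bonds the top atom to the
  atom n−1 positions below.
* **SELFIES dialect** — a valence-constrained total notation on kekulized
  structures: atom tokens carry the bond order to the chain head, capped
  by the remaining valences of both partners; branch and ring tokens read
  base-16 indices (the first 16 alphabet tokens double as digits) and are
  skipped when not realizable; derivation of a region ends when its chain
  head saturates. Every token sequence containing at least one atom token
  derives a chemically valid molecule; aromaticity is recovered by
  sanitization after decoding. Elements span C, N, O, S, P, B and
  halogens with the standard maximum valences (C 4, N 3, O 2, S 6, P 5),
  chosen so RDKit's implicit-hydrogen fill always reaches an allowed
  valence state.

Vocabularies are built from the training corpus and frozen to versioned
text files; the packaged reference vocabularies carry 29 (SMILES), 28
(SELFIES dialect) and 46 (DeepSMILES) structure tokens, with the three
special markers (pad/start/end) recorded separately so either accounting
of "token count" is recoverable. Token sequences are fixed-length 100
(structure tokens, end marker, padding); strings needing more positions
are rejected with an explicit error rather than silently truncated.

## Latent QSAR and applicability domain

Activity labels derive from K_i in nM: molecules with K_i ≥ 10 μM are
excluded from the modeling set, K_i ≤ 100 nM is active, the rest inactive.
Classifiers (SVM with a calibrated decision function so the search
objective is continuous, random forest, XGBoost, MLP) are evaluated by
nested 5-fold cross-validation: outer folds are scaffold-grouped (seeded
shuffle of scaffold groups, greedy assignment to the smallest fold) so no
scaffold straddles evaluation folds, and the inner 5-fold grid search is
refit on each outer-training split. Compact default grids are used
(regularization strength, tree count/depth, hidden sizes) and are
overridable. Reported errors are standard deviations over outer folds.

The distance-to-model (DM) of a query embedding is 1 minus the mean cosine
similarity to its three nearest training embeddings (neighbors ranked by
cosine similarity). The underlying similarity statistic is usually quoted
as a similarity ("SCAvg"); this package reports its distance-oriented
complement so that small DM means close to the training data and the
canonical reliability bins (<0.05, 0.05–0.1, 0.1–0.15, >0.15, half-open)
read in increasing order of risk. Error profiles report the per-bin
distribution of |p(active) − y| and F1.

## Latent search and libraries

Search bounds are μ ± k·σ per latent dimension from a reference embedding
set (k = 2 default; zero-variance dimensions are widened by a configured
epsilon with a warning). The Bayesian maximizer draws `init_points` = 4
scrambled-Sobol probes, then `n_iter` = 20 probes chosen by expected
improvement under a Matérn-5/2 Gaussian process over random candidates in
the current box. With sequential domain reduction the box contracts by a
factor (default 0.9) around the incumbent after every non-improving
iteration, clipped inside the previous box, so box volume is
non-increasing and probes never leave the active box. Non-finite objective
values discard the probe with a warning.

Library generation runs many independent seeded searches and harvests each
incumbent plus every probe whose predicted activity reaches a configurable
floor (default 0.8) — harvesting only incumbents would need one full
search per library member. Validity is accounted over *all* decoded
probes (duplicates flagged, not dropped, so the validity rate is not
biased by deduplication); the deduplicated valid records form the
library. Post-hoc filters keep molecules with QED > 0.5, clogP < 8 and no
ring larger than 7 atoms ("maximum ring size 7" read as ≤ 7 allowed).

Analog generation computes the seed molecule's fingerprint, flips k random
bits in each of n copies, and passes every noised copy through the
deterministic mean-encoder/greedy-decoder path, so output diversity is
attributable to fingerprint noise alone. Latent neighborhoods sample
uniformly on spheres (normalized Gaussian directions scaled to the
radius); interpolation is linear between mean embeddings.

Scaffold novelty scores each generated molecule by the smallest Tanimoto
distance between its Bemis–Murcko scaffold and a reference scaffold set
(novel ⇔ distance ≥ 0.25). The fingerprint used on scaffolds defaults to
ECFP4 and is configurable — the choice shifts the novelty histogram, so it
is recorded with the score.

## Synthetic data

The fixture generator composes two ring-bearing fragments and a short
linker at the SMILES-string level (every fragment attaches through its
first written atom), which guarantees validity by construction, emits
already-standardized strings, and keeps molecular weight controllable
(default window 200–450 g/mol). The activity rule plants a sulfonamide
pharmacophore: pK_i = 6 + 3·1[fragment present] + N(0, 0.3), K_i =
10^(9−pK_i) nM, so actives (~1 nM) and inactives (~1 μM) are separated by
a fingerprint-detectable substructure signal, emulating how real ligand
sets carry substructure-driven affinity differences. Auxiliary generators
provide displaced-Gaussian latent datasets (separable by construction)
and the applicability-domain fixture: a patchy nearest-center labeling
rule with test points pushed off the training support by growing random
displacements, so prediction error grows with distance to model by
construction.

What the synthetic corpus does **not** emulate: the property
distributions, scaffold frequencies, tautomeric/charge diversity and
sheer scale of real ChEMBL/ZINC collections, or measurement noise in
binding assays beyond the Gaussian pK_i term. Passing tests therefore
demonstrate correctness of the machinery and the qualitative phenomena
(posterior-informative embeddings, noise–distance and bounds–validity
trends, DM–error growth) at toy scale, not the quantitative performance
figures attainable on full-scale data.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at deliberately small
scale, chosen as the smallest sizes at which each phenomenon is stable:
50-molecule memorization (200 epochs), a 120-molecule labeled corpus for
the generative trends (250 epochs), 500 synthetic latents for nested CV,
1000 random sequences for totality, five seeds per trend assertion
(evaluated as rank correlations, with constant series counting as weakly
monotone). Training uses float64 throughout; cross-entropy adds 10⁻³⁰⁰
inside the log only as an underflow guard; Sobol initialization uses
scrambling with the run seed; ties in fragment selection and vocabulary
order are broken by sorted order so all artifacts are reproducible.

## Known limitations

* The notation implementations cover the element/charge range of the
  corpus generator (neutral organic subset); exotic elements, isotopes and
  charged species outside neutralization are rejected at conversion, not
  silently mangled.
* The synthetic Klekota–Roth key inventory preserves dimensionality and
  matching semantics but not the published keys' individual identities.
* The NumPy network is CPU-bound and intended for method-scale
  experiments; reference-scale training (10⁶ molecules, width-512 GRUs)
  would require a GPU framework implementation of the same architecture.
* Bayesian search with a classifier objective concentrates probes near
  the applicability-domain boundary; validity of decoded candidates is
  accordingly lower than for test-set reconstruction, and the
  bounds-multiplier sweep trades validity against diversity.
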