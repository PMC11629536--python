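# Methods

## The loop

One experiment interleaves two processes for `R` rounds:

1. **Generation cycle.**  For `N_steps` steps the proposal agent draws a
   batch of `P` molecules, the scoring function evaluates them, molecules
   with total score ≥ the memory threshold enter scaffold-bucketed memory
   (capacity-limited per Murcko scaffold), and the agent's proposal
   distribution is sharpened toward the high scorers.
2. **Active-learning round.**  The round's memory is deduplicated into a
   pool.  For `L` iterations, acquisition scores are computed against the
   *current* predictor (they are recomputed after every fine-tune, so later
   batches benefit from earlier feedback), the top `T` unqueried molecules
   are sent to the expert, the answers are converted to labels and
   confidences, and the forest is refit on the initial data plus all
   feedback.  The updated predictor replaces the old one in the scoring
   function for the next cycle.

Molecules queried once are never re-queried within a run: repeating a
question to the expert wastes the query budget.

A `feedback: false` run is the baseline twin: identical generation cycles,
predictor frozen, expert never called (asserted by call counters).

## Models and assumptions

**Predictor.**  Random forests over Morgan count fingerprints (radius 3,
2048 positions).  The ensemble mean is the prediction; for classification it
is the fraction of trees voting positive (mean of hard votes, not averaged
leaf probabilities).  Treating each tree as a posterior parameter sample is
the standard ensemble approximation that makes information-theoretic
acquisition tractable; it underestimates posterior diversity when trees are
correlated.

**EPIG.**  For binary per-tree outcomes, the joint distribution of
`(y, y*)` over the `B` trees is a 2×2 table, and the mutual information is
computed in closed form; the expectation over the target distribution is an
exact weighted sum over its members (top-`k` pool molecules weighted by
transformed score), never Monte-Carlo.  Regression tree outputs are
binarized through the scoring transform at 0.5 — "predicted inside the
desired property range" — which aligns the information measure with the
semantics of the score-weighted target distribution.  A Gaussian-mixture
treatment of continuous outcomes would be the natural refinement but is out
of scope.

**Feedback.**  Classification agreement `a` maps to label `1{a ≥ 0.5}` with
confidence `max(a, 1−a)`; the tie `a = 0.5` maps to label 1, where its
weight (0.5, the minimum) makes the choice nearly inert.  Regression experts
return an unbounded noisy value, used directly as the label with unit
confidence, since no confidence notion exists on an unbounded scale.
Fine-tuning is a weighted refit from scratch: initial records at `1/N0`
each, each acquired batch of size `T` at `u_t/T` per record, so every batch
keeps its own normalization across rounds.  Zero-weight records are dropped
before fitting, which makes zero-confidence feedback bit-identical to
refitting on the initial data alone at a fixed seed.

**Experts.**  Simulated experts add seeded Gaussian noise to a deterministic
oracle; probability-valued oracles clip the noisy value to [0, 1].  Noise
draws come from a dedicated stream per expert, independent of generator and
acquisition randomness.

**Generator stand-in.**  The production system optimizes a SMILES RNN by
policy gradient; its loss (squared gap between reward-augmented prior
log-likelihood and agent log-likelihood, `λ` defaulting to 128, or 180 in
multi-objective settings) is provided as a pure function with the
augmented-likelihood sign convention `log p_prior + λ s` (a flag exposes the
opposite sign).  The default agent instead reweights a fixed library:
proposals are drawn with replacement proportionally to per-molecule weights,
and accepted batches update `w ← w · exp(η s)`.  This preserves the property
the loop needs — proposal quality is nondecreasing under a static scorer —
while staying exactly reproducible.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `R` / `n_steps` / `P` | 3 / 40 / 128 | rounds, generator steps per cycle, proposal batch size |
| `L` / `T` | 2 / 10 | acquisition batches per round, queries per batch |
| `top_k` | min(1000, pool) | target-distribution size for EPIG |
| `sigma_eps` | 0 | expert noise sd (1.0 is a moderate regression expert; 0.15–0.7 spans classification noise) |
| `eta` | 0.1 | agent step size; 1.0 collapses the proposal distribution onto a handful of molecules within one desk-scale cycle, destroying the pool the AL round needs, while 0.1 keeps pools at a few hundred molecules and still raises mean proposal scores |
| forest | 300 trees (regression); 200 trees, depth 10 (classification) | standard QSAR/QSPR forest sizes |
| memory | capacity 25/scaffold, threshold 0.4 | diversity-filter knobs |
| `library_size` / `n_initial` | 5000 / 200 | fixture library and initial labeled set |
| `n_initial_scaffolds` | 2 | scaffold families the initial data is drawn from (None = uniform) |
| transform | double sigmoid over [2, 4], steepness 10 | reward plateau for range-targeted regression; steepness 10 makes the plateau sharp but finite |

The double sigmoid is `logistic(k(x−low)) · logistic(−k(x−high))`: ≈1 well
inside `[low, high]`, 0.5 at each boundary, →0 outside.  Classification
predictor components use the identity transform, since vote fractions are
already probabilities.

## What the synthetic data emulates — and what it does not

The fixture library enumerates ~7,600 molecules from 20 ring scaffolds ×
30 substituents, canonicalized, deduplicated and seed-shuffled.  It gives
valid, scaffold-diverse chemistry without a trained generative model, but
its chemical space is tiny and grid-like: fingerprint overlap between
molecules is far higher than in a ChEMBL-scale corpus, and "novel" chemistry
cannot emerge — the generator can only re-rank the library.

The synthetic linear oracle (`w·fingerprint + bias`, weights on 64 active
positions, rescaled to mean 3 and sd 2 over the library) makes ground truth
exactly recoverable in principle, which is what a parameter-recovery study
needs.  Real property landscapes are neither linear nor noiseless in the
features.

The initial labeled set is drawn from the fewest largest scaffold families
that can supply `n_initial` molecules (default 2 families).  This mirrors
early-project reality — small, scaffold-narrow assay datasets — and it is
what creates the generalization gap the loop exists to close.  With a
uniform initial draw over this small library, the initial forest already
covers the whole space and active learning has nothing to fix; noisy
feedback can then only inject label noise at evaluated molecules.  Passing
recovery tests therefore show that feedback closes an applicability-domain
gap under the stated conditions; they do not show that the method improves
an already well-covered predictor, nor do they quantify behavior on
RNN-scale chemical spaces.

## Numerical choices

- Entropies and mutual information in nats; `0·log 0 := 0`; MI clamped at 0
  against floating-point negatives (≤1e−16).
- The MI joint is computed vectorized as `p11 = O O*ᵀ/B` with marginals by
  row means, matching brute-force enumeration to 1e−12 (tested for B ≤ 8).
- Ranking ties (acquisition batches, target-distribution membership,
  top-pool evaluation sets) break by canonical SMILES lexicographic order,
  making every ranking deterministic.
- Labels threshold strictly (`value > δ` is positive; `value = δ` is
  negative).
- Degenerate target distributions (all top-k scores zero) raise; the
  orchestrator explicitly falls back to a uniform distribution over the
  top-k rather than silently.
- Randomness is split across four named streams — generator (library +
  initial-data draw + proposals), forest, expert, acquisition — so ablating
  one source leaves the others' draws unchanged.
- Run logs round recorded floats to 10 decimals purely for readability;
  reruns with identical config and seeds are byte-identical.

## Evaluation

Per round, the mean absolute error between ensemble predictions and oracle
values is computed on the top-100 pool molecules by total score (against
the oracle, never against the noisy expert), before and after fine-tuning.
The metric suite for generated sets follows distribution-learning benchmark
conventions: internal diversity = 1 − mean pairwise Tanimoto (presence
bits, ordered pairs i ≠ j), SNN = mean nearest-neighbour similarity to a
reference set, Frag = cosine similarity of BRICS fragment count profiles,
novelty and uniqueness as set fractions, plus mean synthetic-accessibility
and QED scores.

## Known limitations

- The library-reweighting agent cannot extrapolate beyond its library; the
  policy loss is exposed for plugging in a real sequence generator, but no
  RNN is included.
- Multi-task predictors are not supported; in multi-objective runs only the
  named predictor component is fine-tuned.
- Regression feedback carries unit confidence; a principled confidence for
  unbounded estimates would need an explicit expert error model.
- Platt calibration applies to binary classifiers only.
- The fragment-distribution metric depends on BRICS decomposability; rigid
  molecules with no breakable bonds contribute themselves as single
  fragments.
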