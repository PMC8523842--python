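# Methods

## Problem and encoding

Channel selection for a hybrid MI+SSVEP interface is posed as multiobjective
maximization over binary masks of length K (= 15 for the default montage
FC3, FC4, C5, C3, C1, Cz, C2, C4, C6, CP3, CP4, POz, O1, Oz, O2). The
montage splits into a motor block (channels 1–11, 1-based) and an occipital
block (12–15); these block boundaries drive the stage-2 analysis and are
configurable. Objectives are MAR and SAR — the two tasks' classification
accuracies, both in [0, 1] — and NC = K − C with C the selected-channel
count, so *all* objectives are maximized and dominance is the strict Pareto
relation (at least as good everywhere, strictly better somewhere). The
empty mask is defined to score accuracy 0 on both tasks at no evaluation
cost, keeping every operator total.

## Objective backends

**MAR.** Epochs are zero-phase band-passed to 5–30 Hz (4th-order
Butterworth, forward–backward, applied once to the full montage so per-mask
work is just channel restriction). CSP filters come from the generalized
eigenproblem `S1 w = λ (S1 + S2) w` of the class-average trace-normalized
covariances; eigenvalues lie in [0, 1] and the B-orthonormalization whitens
the projected composite covariance. The backend keeps m = min(2, ⌊C/2⌋)
filter pairs; features are normalized log variances (scale-invariant). A
single-channel mask skips CSP and uses the lone channel's log variance.
Classification is an RBF-SVM with C = 1 and kernel width from the median
heuristic on the training features; accuracy is the mean over stratified
5-fold cross-validation (fixed fold seed, CSP and SVM fit on training folds
only, fold count reduced with a warning when a class is smaller than 5).
Rank-deficient composite covariances are ridge-regularized with
ε = 1e-8 · trace/dim and a warning.

**SAR.** Per trial, the largest canonical correlation against sine/cosine
references at each stimulus frequency and its harmonics (2 by default),
computed from orthonormal bases (SVD, dropping numerically null
directions) and the SVD of their cross-product; the predicted frequency is
the argmax with ties (within 1e-12) broken to the lowest index. CCA needs
no training, so SAR is the fraction correct over all trials.

**Ledger.** A run-wide ledger caches values by (mask bytes, task) and
counts each distinct computation against the budget (default 10000); cache
hits are free, so the budget counts distinct (mask, task) evaluations. The
same mask scored for both tasks costs two. When the budget is exhausted a
fresh evaluation returns "unavailable" and the caller drops that solution.

## Stage 1 — evolutionary multitasking

Population of N = 100 random masks (each bit set when its U[0,1] draw
exceeds 0.5) with labels uniform on {1, 2}; each individual is evaluated
only on its own task's (accuracy, NC) pair. Per generation: binary
tournament selection with replacement (non-domination rank within the
individual's own task group, then crowding distance, then a seeded coin);
consecutive pairing of parents; same-label pairs always recombine, while
mixed-label pairs recombine with probability pc = 0.8, otherwise mutate
with probability pm = 0.2 (per-bit flip rate 1/K), otherwise pass through
unchanged — the only side-effect-free completion of that branch. Offspring
inherit their positional parent's label. Environmental selection keeps N
survivors with per-label quotas proportional to each label's share of
parents + offspring (objective values of different tasks are never compared
directly); within a label, whole fronts by rank and the cut front by
descending crowding distance. After selection, label-1 survivors update
PS_MI and label-2 survivors PS_SSVEP. Archives are capped at 100 by
iterative lowest-crowding removal with recomputation after each removal
(ties: earliest insertion survives); objective-space duplicates with
distinct masks are retained — users want all minimal subsets — but each
mask appears at most once per archive.

Stage 1 is allotted 90% of the budget (configurable). Termination is
budget-driven; because K = 15 admits only 2^15 masks, a converged
population can stop producing new distinct masks long before the allotment
is spent, so the loop also stops after 25 consecutive generations without a
new distinct evaluation. This guard only ever ends a run *under* budget.

## Stage 2 — variable analysis and local search

For each motor-block channel j and each PS_MI member x: toggle bit j; if
toggling 0→1 raises MAR the channel gets +1, if it lowers it −1; toggling
1→0 votes with the opposite signs; unchanged accuracy casts no vote. The
tally's sign puts j in the add (positive), delete (negative) or invalid
(zero) group. Occipital-block channels are voted the same way over
PS_SSVEP with SAR. Toggled evaluations draw on the ledger like any other.
Local search gives each PS_MI member one uniformly drawn channel r from the
occipital block — set it if r is in the add group and unset, clear it if in
the delete group and set — and symmetrically for PS_SSVEP members with r
from the motor block; one candidate per member. The final set evaluates
MAR *and* SAR for every archive member and candidate and keeps the
non-dominated solutions under (MAR, SAR, NC), capped at 100. Solutions
whose missing cross-task accuracy cannot be computed within the budget are
dropped with a warning. The analysis + search pass runs once by default
(configurable), with the final assembly after the last pass.

## Synthetic data

The generator plants a recoverable ground truth at 256 Hz with 2 s trials:

- **MI** (20 trials/class): a 10 Hz mu oscillation at amplitude 2.0 on C3
  and C4 over unit-amplitude 1/f noise (exponent 1) on all channels;
  the hemisphere contralateral to the imagined hand is attenuated by the
  ERD depth 0.8 (left-hand imagery quiets C4 and vice versa), with random
  phase per trial. ERD-by-attenuation, rather than additive activation,
  matches the desynchronization physiology the CSP pipeline assumes.
- **SSVEP** (10 trials/class): stimulus set {10, 12, 15} Hz with 2
  harmonics (amplitudes 1.0 and 0.5) at overall amplitude 1.5 on O1, Oz,
  O2, random phase per trial, same 1/f background.

Trial counts and SNRs are chosen for desk-scale testability: high enough
that planted channels support ≥ 0.9 task accuracy, low enough off-target
that uninformative masks stay near chance. The generator does not model
volume conduction, artifacts, inter-subject variability or
non-stationarity, so passing tests demonstrate algorithmic correctness and
planted-signal recovery — not expected accuracy on recorded EEG.

## Numerical and design choices

- All randomness flows through one `numpy` Generator seeded from the run
  config; runs are byte-reproducible (result CSVs are sorted
  deterministically; manifests carry timings and are not byte-stable).
- Crossover cut points are drawn uniformly from 0..K inclusive; on binary
  strings the positional partially-mapped operator reduces exactly to this
  segment exchange.
- "Mutation probability 0.2" is read as the per-pair trigger; the per-bit
  flip rate is a separate knob defaulting to 1/K.
- Crowding distance: boundary members infinite; interior members sum
  neighbour-gap / objective-range per objective; zero-range objectives
  contribute nothing; fronts of size ≤ 2 are all-infinite.
- Accuracy comparisons in the stage-2 voting use exact equality — accuracies
  are ratios of small integer counts, so "unchanged" is well-defined.
- Channel indices are 1-based in every user-facing report and 0-based
  internally.
- Problem sizes in the test suite (population 20–40, budgets in the
  hundreds, 10-seed recovery studies) are desk-scale choices; the default
  configuration (population 100, budget 10000) is exercised end-to-end in
  the budget-accounting check and the acceptance script.

## Known limitations

- The cross-validated MAR is a stand-in for whatever held-out protocol a
  lab would use; absolute accuracies depend on it.
- SVM hyperparameters are fixed (C = 1, median-heuristic width); no tuning.
- With K = 15 the search space is small enough that the budget rarely
  binds; the budget machinery matters for larger montages.
- Stage 2's voting is only as stable as the archives it analyzes; early or
  tiny archives can mislabel channels, which the single guided toggle per
  member then propagates (mildly — the final non-dominated filter never
  loses an archive solution that remains non-dominated).
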