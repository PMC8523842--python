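# emmoa — multiobjective EEG channel selection for hybrid BCIs

Hybrid brain-computer interfaces decode two EEG modalities at once: motor
imagery (MI), which shows up as lateralized mu/beta desynchronization over
motor cortex, and steady-state visual evoked potentials (SSVEP), occipital
oscillations at a flickering stimulus's frequency. Practical systems want
as few electrodes as possible without giving up accuracy on *either* task —
a three-way trade-off between MI accuracy, SSVEP accuracy, and channel
count that has no single best answer, only a Pareto front.

`emmoa` searches that front with a two-stage evolutionary-multitasking
algorithm over binary channel masks `x = [x1, …, xK], xi ∈ {0,1}`:

- **Objectives** (all maximized): `MAR`, the MI classification accuracy of
  a CSP + RBF-SVM pipeline under stratified cross-validation; `SAR`, the
  SSVEP accuracy of canonical-correlation (CCA) frequency decoding against
  sine/cosine references at each stimulus frequency and its harmonics; and
  `NC = K − C`, the number of *unselected* channels.
- **Stage 1 — multitasking search.** One population whose individuals carry
  a task label (1 = MI, 2 = SSVEP) and are scored only on their own task's
  two-objective problem, (MAR, NC) or (SAR, NC). Tournament selection,
  two-point segment-exchange crossover and flip-bit mutation produce
  offspring that inherit their positional parent's label; mixed-label
  pairs are the conduit for cross-task transfer. The stage maintains one
  crowding-distance-capped Pareto archive per task (PS_MI, PS_SSVEP).
- **Stage 2 — decision-variable analysis + local search.** Each channel is
  voted into an add / delete / invalid group by toggling its bit across
  archive members and watching the task accuracy (motor-block channels are
  judged on the MI archive, occipital-block channels on the SSVEP
  archive). Each archive member then takes one guided toggle in the
  *other* task's block, and the final Pareto set is the non-dominated
  filter of everything under the full (MAR, SAR, NC) view.

Every distinct (mask, task) accuracy computation is charged against a
global evaluation budget (default 10000); cached re-evaluations are free.

A synthetic hybrid-EEG generator with planted informative channels
(contralateral ERD on C3/C4, stimulus harmonics on O1/Oz/O2, 1/f
background) makes the whole method testable without recordings.

## Worked example

```sh
emmoa run --synthetic --seed 7 --pop-size 40 --budget 1000 --out demo
emmoa summarize demo
```

prints

```
final Pareto set: 7 solutions; 284/1000 evaluations used
manifest: demo/manifest.json
  MAR      SAR  Number of selected channels
0.000 0.000000                            0
1.000 0.333333                            1
0.575 0.366667                            1
0.550 1.000000                            1
1.000 1.000000                            2
1.000 1.000000                            2
1.000 1.000000                            2
```

Each row is one non-dominated channel subset. On the planted synthetic
data the search recovers the ground truth: single channels specialize (C3
alone decodes MI perfectly but leaves SSVEP at chance ≈ 1/3; O2 alone does
the reverse), and two-channel subsets pairing one motor with one occipital
electrode (`final_ps.csv` shows C4;O2, C4;O1, C3;O2) reach perfect
accuracy on both tasks — the compromise the method exists to find. The run
directory also holds the per-task archives (`ps_mi.csv`, `ps_ssvep.csv`),
the variable-group report, and a manifest with the evaluation accounting.

The same pipeline runs on recorded data via `--mi-data` / `--ssvep-data`,
each a `<stem>.npy` trials × channels × samples array with a `<stem>.json`
sidecar (labels, sampling rate, channel names; stimulus frequencies for
the SSVEP set). `emmoa synth --out DIR` writes a canonical fixture pair in
that format.

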