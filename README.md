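# emgsyn

Muscle-synergy analysis of multi-channel surface EMG for complex motor
tasks: envelope processing, non-negative matrix factorization (NMF) with
best-of-restarts selection, synergy-number selection by dual
variance-accounted-for criteria, inter-participant variability
quantification, cross-entity reconstruction with randomized nulls, and
shared-synergy statistics — plus a seeded synthetic-EMG generator with
known ground truth so the whole chain is testable without recordings.

It is written for movement scientists who record multi-muscle EMG during
trials of a repeated movement (the emulated design: 7 participants x 3
movement variants x 6 trials, 16 lower-limb muscles at 1000 Hz) and want
to ask: how many synergies does each movement need, how variable are they
across people, and which synergies are shared across movements?

## The model

Muscle activity is modeled as a small set of co-activated muscle groups.
For each participant and task the concatenated, amplitude-normalized
envelope matrix `E` (m muscles x n timepoints) is factorized as

    E ≈ W C,   W ≥ 0 (m x k),  C ≥ 0 (k x n)

where the synergy vectors `W` (columns scaled to max 1) give the muscle
weightings and the activation coefficients `C` their recruitment over
time.  Reconstruction quality is the total variance accounted for,

    tVAF = 100 (1 − ‖E − W C‖²_F / ‖E‖²_F).

The number of synergies (NoS) is the smallest k with tVAF > 90% whose next
synergy adds ≤ 1 percentage point; the study-wide count (NoSoA) is the
rounded mean NoS.  Synergy pairs count as similar/shared when CosSim > 0.8,
Pearson r exceeds the critical value for the muscle count (0.623 for 16
muscles at p = 0.01), or lagged cross-correlation r_max > 0.9.  Shared
synergies across two tasks are matched one-to-one by descending r, with

    %n_shared = 100 · n_shared / (k₁ + k₂ − n_shared).

Cross-entity reconstruction fixes one entity's `W` (or `C`) and refits the
other factor to a different entity's envelopes by non-negative least
squares; comparing the resulting tVAF_rec with a seeded random-matrix
null (tVAF_rand) separates genuine shared structure from chance.

## Worked example

`examples/` contains one short script per capability.  Extracting
synergies from a generated study and scoring recovery
(`examples/03_extract_synergies.py`):

```text
envelope matrix (16, 600) -> W (16, 4), C (4, 600)
tVAF at k=4: 98.90% (restart 4 of 10 won)
recovery CosSim vs ground truth per synergy: [0.996 0.995 0.997 0.996]
  synergy 0: dominant muscles ['glut_med_f', 'rect_fem_b', 'sem_tend_f']
```

The factorization explains 98.9% of the envelope variance with 4
synergies, and each recovered synergy vector matches a ground-truth
column almost perfectly (CosSim ≈ 1 after optimal matching).  The
reconstruction-null comparison (`examples/06_reconstruction_null.py`)
prints the characteristic ordering

```text
mean tVAF (own joint fit):         98.90%
mean tVAF_rec (real other source):  97.28%
mean tVAF_rand (random source):     49.51%
```

— a real participant's synergies explain another participant's data far
better than random non-negative matrices, i.e. the shared structure is not
chance.  A full pipeline run (`examples/08_full_pipeline.py`, or
`emgsyn simulate` / `emgsyn run` from the shell) writes every tidy result
table (tVAF curves, NoS selection, CoV summary, pairwise similarity,
reconstructions, nulls, shared-synergy counts) plus a JSON run report.

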