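# Methods

This note documents the scientific model implemented by `rfmqa`, the
default parameters and why they were chosen, the scope of the synthetic
data generator, and the numerical decisions that affect results.

## Problem statement

Given a pool of candidate 3D models (decoys) for one protein target,
single-model quality assessment asks which decoy is closest to the
(unknown) native structure. `rfmqa` treats this as regression: a random
forest predicts each decoy's *relative* TM-score within its pool from
nine structure- and sequence-derived features, and the pool is ranked by
the prediction. Because both features and labels are min-max normalised
per pool, the method is a relative ranker — predicted scores are
comparable within a pool, not across pools.

## Features

For a decoy `m` of target `t`:

* **F1–F3 — statistical-potential energies.** Normally imported from
  external scoring programs as two-column `(model_id, energy)` tables,
  with the convention lower = better (a `negate` switch accommodates
  the opposite sign). Units are irrelevant after per-pool
  normalisation. A built-in CA contact pseudo-energy (clash penalty
  below 4 Å; hydropathy-weighted favourable band 4–8 Å, sequence
  separation ≥ 3) makes the pipeline runnable with no external binary;
  it claims no accuracy beyond "compact beats stretched".
* **F4–F6 — SS match fractions.** The model's secondary structure is
  assigned geometrically: Kabsch–Sander hydrogen bonds
  (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol,
  amide H rebuilt from the previous peptide plane), helices from
  consecutive i→i+3/4/5 turns, strands from parallel/antiparallel
  bridge patterns, reduced to 3 states (H,G,I→H; E,B→E; else C). The
  fractions count positions where model and sequence-based prediction
  agree on H, E and C respectively, each divided by chain length.
  DSSP output files are also accepted directly.
* **F7 — confidence-weighted SS consistency.**
  `(1/N) Σ δ(ss_obs_i, ss_pred_i) · conf_i`, confidences in [0, 1]
  (PSIPRED `.ss2` probabilities or integer 0–9 scores scaled by 9).
  An alternative normalisation by `Σ conf_i` is available
  (`consistency_norm="confidence"`); the variant is part of the model
  hash because it changes the feature's meaning.
* **F8–F9 — ASA consistency.** Per-residue absolute solvent-accessible
  surface area of the model is computed with the Shrake–Rupley
  algorithm (golden-spiral point sets, probe 1.4 Å, vdW radii C 1.70,
  N 1.55, O 1.52, S 1.80 Å) and compared to a sequence-based
  prediction by Pearson correlation (F8) and cosine similarity of the
  nonnegative vectors (F9). Relative predicted ASA is converted to
  absolute via the Tien max-ASA table.

## TM-score engine

TM-score of a decoy against a reference of length L is
`max over superpositions of (1/L) Σ 1/(1 + (d_i/d0)²)` with
`d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5) Å`. The maximisation uses the
standard heuristic: seed superpositions from contiguous fragments of
lengths L, L/2, L/4 and L/8 (start step = fragment/4), then alternate
(a) Kabsch superposition on the currently selected residue set and
(b) reselection of residues within a distance cutoff (starting at
max(d0, 3.0) Å and grown by 0.5 Å until ≥ 3 residues qualify) until the
selected set repeats. Kabsch uses the SVD construction with the
determinant sign correction, so reflections are never returned.
Against a 500-restart brute-force oracle the engine agrees to ≤ 0.004
for scores above 0.15; on essentially random decoys (score < 0.15) it
may undershoot by up to ~0.03, which is irrelevant for ranking
decoys of usable quality.

## Random forest

Implemented from scratch (regression CART + bagging) so the protocol is
fully transparent:

* bootstrap samples of size n per tree; out-of-bag (OOB) rows give the
  error estimate and permutation importance;
* `m_try` features drawn per node; split criterion is variance
  reduction (decrease in sum of squared deviations), the regression
  analogue of the impurity-decrease rule; candidate thresholds are
  midpoints of consecutive distinct sorted values; growth stops below
  `node_cutoff = 5` rows; no pruning;
* determinism: ties go to the lowest feature index then the lowest
  threshold; each tree derives its RNG stream from
  `SeedSequence(entropy=seed, spawn_key=(tree_index, stream))`, so
  enlarging `n_tree` never changes trees already grown, and two fits
  with the same seed are bit-identical;
* importance is Breiman's raw permutation importance: mean over trees
  of the OOB-MSE increase after permuting one feature among that
  tree's OOB rows.

A numerical guard excludes midpoint thresholds that round up to the
upper neighbouring value (possible when two values are within one ulp,
which per-pool normalisation makes likely); without it a split can
produce an empty child and NaN leaf values.

## Training protocol

1. **Screening (training only).** Pools with mean TM < 0.3 are
   discarded; within surviving pools only the top `ceil(0.5·n)` models
   by TM are kept, so the regressor does not spend capacity on
   hopeless decoys. Test pools are never screened.
2. **Per-pool normalisation** of the nine features and the label.
3. **Cross-validation.** Targets (never individual models) are
   randomly partitioned into 5 folds. Per fold the hyperparameter grid
   n_tree ∈ {500, 1000, …, 10000} × m_try ∈ {1…7} (140 combinations)
   is searched; the winner minimises the forest's aggregated OOB MSE,
   with ties to the smaller n_tree. OOB MSE was chosen as the search
   criterion because it needs no further data split and is an unbiased
   estimate of generalisation error; it keeps the grid search inside
   the training folds.
4. **Final model.** Defaults n_tree = 3000, m_try = 1.
5. **Ranking.** An unscreened, normalised pool is scored by the
   forest; ties in the predicted score are broken by model id.

The feature order and normalisation variant are hashed (sha256, 16 hex
chars) into serialized models; `rfmqa rank` refuses a model whose hash
does not match its configuration.

## Evaluation metrics

Over a set of labelled pools and one selection per pool: CC_TM
(Pearson between selected and best TM across targets), Spearman of the
same two vectors (classic 1 − 6Σd²/(n(n²−1)) without ties; mean ranks
and Pearson-on-ranks with ties), TM_loss (TM_best − TM_selected),
selection Z-score ((TM_selected − pool mean)/pool sd, sample sd
ddof = 1 by default with a population option — a uniform-random pick
has expected Z ≈ 0), the Z histogram over bins (−∞,0), [0,1), [1,2),
[2,3), [3,∞), CC_rank (mean per-pool Spearman of predicted scores vs
labels), and pairwise gain/loss/equal counts between two methods.

## Synthetic data generator

The generator replaces external decoy sets and predictor outputs with
controllable stand-ins. It is an *emulation of study conditions*, not
of protein physics:

* **References.** Backbone (N, CA, C, O) built by natural-extension
  reference frame placement with ideal bond lengths/angles
  (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; ω = 180°) and
  imposed torsions: helix (−57, −47), helix-loop-helix, or an
  antiparallel strand pair joined by a two-residue turn with torsions
  (60, 60)/(90, 0), chosen so the Kabsch–Sander assignment recovers a
  genuine bridge ladder. Sequences are drawn uniformly from the
  standard residues minus proline.
* **Decoys.** Per-residue rigid Gaussian displacement of all four
  backbone atoms, one decoy per noise sigma. The default sigma ladder
  spans 0.4–1.6 Å, calibrated so that 30-residue pools have mean TM
  ≈ 0.5 — realistic mid-quality pools that survive the 0.3 screening
  threshold without containing the native itself.
* **Predictions.** The SS "predictor" copies the reference assignment
  at accuracy 0.8, with confidences drawn U(0.7, 1) where correct and
  U(0.3, 0.7) where wrong; the ASA predictor adds N(0, 15 Å²) noise to
  the reference ASA (clamped at 0).
* **Energies.** Each of the three pseudo-energy tables is
  `ρ·z + √(1−ρ²)·ε` on the standardised badness z = std(1 − TM), with
  ρ = 0.7 by default, affinely mapped to an energy-like scale. ρ
  controls how informative the energy features are and is the lever
  behind the "beats the single-energy baseline" acceptance property.
* All streams derive from one seed via fixed `spawn_key`s (reference,
  decoys, predictions, energies), so every artifact is reproducible
  and independent of how many other artifacts were generated.

Default problem sizes used by the acceptance experiment (30 training
pools + 10 test pools, 30 residues, 8 decoys, 300 trees) were chosen to
keep a full run around 20 s on one CPU while leaving all qualitative
effects (forest ≫ random, forest > single energy) intact; they are a
package choice, not a claim about realistic benchmark scale.

## Numerical choices

* ASA point counts: 960 sphere points by default (≲ 0.5% quadrature
  error, matches an independent implementation to < 2% per residue);
  the pool generator uses 240 points for speed. Because the point set
  is fixed in the laboratory frame, ASA is rotation-invariant only to
  ~1% at 960 points.
* Pearson/Spearman return NaN with a warning on zero-variance input;
  constant normalisation columns map to 0 with a warning (a pool where
  a feature does not vary carries no ranking signal in that feature).
* A single-model pool normalises to all-zero features with a warning
  and is rankable (trivially).
* TM-score pair lists, fold assignments and rank orders all have
  deterministic tie-breaks (lowest index / lexicographic model id).

## Limitations

* The built-in contact potential is a placeholder; real use should
  import dDFIRE/RWplus/GOAP (or comparable) score tables.
* Synthetic decoys are rigid-jitter perturbations — no compaction,
  misfolding or register shifts — so feature–quality relationships are
  cleaner than on real decoy sets; results on real benchmark data
  (e.g. CASP server models) will be substantially harder.
* The SS assignment implements the Kabsch–Sander core (turns and
  bridges) without the full DSSP edge-case catalogue (chain breaks,
  π-helix preference variants); agreement with an independent DSSP is
  exact on ideal fixtures but can differ on borderline residues.
* TM-score may undershoot the global optimum on near-random decoys
  (score < 0.15) by up to ~0.03.
* The forest is trained on pools screened to their top half, so
  predicted scores for very poor decoys are extrapolations; rankings
  among the bottom of a pool are less reliable than the top pick.
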