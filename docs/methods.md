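# Methods

## The prediction problem

The positive class (ECM) is a small set of secreted, domain-rich proteins;
the negative class (intracellular proteins) outnumbers it by roughly 21:1 in
curated training corpora (521 vs 11,336 in the reference corpus whose shape
the defaults mirror). Accuracy is therefore uninformative — a constant
"nonECM" answer scores ~95% — and balanced accuracy `BAcc = (Sn + Sp)/2` is
the headline criterion throughout.

## Feature families

**Domain flags (63).** One binary feature per catalog domain, 0 when the
domain is annotated on the protein and 1 otherwise. This inverted-looking
polarity is kept as the published encoding; `polarity="presence"` gives the
complement. Tree ensembles are invariant to the polarity of a binary split,
so the choice does not affect performance — the switch exists so feature
tables read naturally either way. Domain truth comes from an offline
(protein → accession) annotation file, never from live database queries.

**Physicochemical means (24).** The mean amino-acid-index value per
property. Unknown residues (`X`, which real sequence databases contain) are
excluded from the mean with the effective length reduced; an all-`X`
sequence is an error rather than a silent NaN.

**PSSM grey-model descriptor (80).** The `L × 20` integer log-odds matrix is
mapped through the logistic function, giving values in (0, 1) — strictly
positive, which the grey model's cumulative sum requires — then each column
yields its mean and a GM(2,1) coefficient triple, 20 + 60 = 80 values. The
GM(2,1) fit builds the cumulative series `x1`, the first differences
`α(k) = x0(k) − x0(k−1)` and the consecutive means
`z1(k) = (x1(k)+x1(k−1))/2`, and solves rows `[−x0(k), −z1(k), 1] · θ = α(k)`
for `θ = (a1, a2, b)` by least squares. The minimum-norm (pseudo-inverse)
solution is used so that rank-deficient systems — a constant column is a
legal input and yields exactly (0, 0, 0) — are well defined instead of
crashing. Proteins shorter than 4 residues have no descriptor (fewer than 3
difference equations) and are refused with an explicit message; likewise
proteins whose PSSM is missing. PSSM rows at `X` positions are kept as-is,
since PSI-BLAST emits them.

An alternative standardization (per-protein z-scoring) would break strict
positivity and was not pursued; the logistic map is the conventional choice
for PSSM-derived grey-model descriptors. The descriptor is isolated behind
`pssm_features` so a different 80-D construction can be swapped in.

## Feature selection

mRMR uses the difference (MID) criterion with plug-in mutual information in
bits over discretized features: binary columns pass through, continuous
columns are three-binned at mean ± 1σ (the standard preprocessing in the
protein-feature literature; a zero-variance column becomes a single code
with MI 0). Ties in the greedy objective are broken by input column order,
making the ranking fully deterministic.

IFS evaluates every nested top-k subset with the *same* stratified fold
partition, so the curve reflects k, not fold noise. The optimal subset is
the smallest k attaining the maximal BAcc. The ranking fed to IFS is
computed once on the full dataset, mirroring the original protocol; the
cross-validation inside each subset evaluation never uses held-out labels
(see Leak hygiene). `--max-k` truncates the curve for desk-scale runs.

## Under-sampling ensemble

`K = floor(n_neg/n_pos)` by default (21 at the reference corpus shape).
Negatives are shuffled once per training call and split into K disjoint
subsets whose sizes differ by at most one (leftovers spread one per subset);
each base learner is a 500-tree random forest with `mtry = √p`, trained on
all positives plus one subset. Disjoint coverage means every negative is
used exactly once — no information discarded, no learner sees an imbalanced
problem. Combination is probability averaging (soft voting), which produces
the continuous ECM probability that the 0.7 confidence threshold is applied
to; hard majority voting would not. With balanced data K collapses to 1 and
the ensemble is exactly a single random forest. Per-learner seeds fan out
from the run seed via `numpy.random.SeedSequence([seed, j])`, so results are
bit-reproducible and learners are independent.

## Evaluation protocol

Stratified k-fold CV (k = 10 by default; per-class fold counts differ by at
most one). Held-out predictions from all folds are pooled into one confusion
matrix before computing metrics — with only ~52 positives per fold at
reference scale, per-fold metric averaging would be noisy and occasionally
undefined. The identity `Acc = (n_pos·Sn + n_neg·Sp)/(n_pos+n_neg)` is
asserted on every report. Presentation rounding is 4 decimals (Python's
round-half-even); internal values are never rounded.

The imbalance experiment trains a *single* plain forest (no ensemble) at
negative:positive ratios 1..21, redrawing the negative subsample each
repeat, to demonstrate raw imbalance damage; the ensemble-vs-no-ensemble
comparison is the same CV path with K = auto vs a single forest on the full
imbalanced data.

### Leak hygiene

Everything derived from training data — forest fitting and the negative
partition — is recomputed inside each training split. Two tests enforce
this: fold training sizes must exactly exclude the held-out fold, and
flipping the labels of one held-out fold must leave that fold's predictions
bit-identical (any peek at held-out labels would change them). A static
"canary feature informative only in test folds" cannot exist — every sample
is held out exactly once, so such a feature equals the label everywhere —
hence the label-flip formulation. Null-signal data additionally pins CV
BAcc to 0.5 ± 0.05.

## Synthetic data generator

The generator emulates the statistical structure the features assume, with
independent class signals per family:

- **Domains**: each catalog domain assigned independently with probability
  `p_domain_pos` (default 0.05, ≈3 domains per positive, ~96% of positives
  carry at least one — real ECM proteins carry a handful of hallmark
  domains) vs `p_domain_neg` (default 0.002).
- **Composition**: glycine/proline/cysteine mass scaled by
  `1 + composition_shift` (default 0.5) in positives — a collagen-like bias
  that moves the physicochemical means.
- **PSSM**: integer scores from a rounded N(0, 3) clipped to [−10, 10]
  (PSI-BLAST's typical log-odds range); positives get a `pssm_signal`
  offset (default 2.0) on five fixed columns (G, P, C, W, Y), emulating
  class-specific conservation. Sequences contain rare `X` residues
  (p = 0.002) so unknown-residue handling is exercised.

Default class sizes are 100 positives / 2,100 negatives — the reference
corpus's 1:21 imbalance at desk scale. `SimConfig.null()` removes all three
signals (chance-level data); `SimConfig.moderate()` weakens them
(`p_domain_pos` 0.02 vs 0.006, shift 0.15, signal 0.5) so that classifiers
cannot saturate and imbalance effects stay visible — saturated classes would
mask the ensemble-vs-single-forest contrast the moderate conditions exist to
measure.

Not emulated: domain co-occurrence structure, homology between sequences,
positional structure along the PSSM, label noise. Passing tests on this
data demonstrate pipeline correctness and the directional claims
(imbalance hurts a single forest; the ensemble repairs it), not real-data
accuracy. Real-corpus performance additionally depends on externally
computed PSI-BLAST profiles and curated annotations, which is why the
reference figures (Sn 0.8925, Sp 0.9360, BAcc 0.9142 with the top 151 of
167 features) are documented constants here, not reproduced quantities.

`truth.json` always records the full generator configuration and
per-protein ground truth, so downstream checks assert recovery without
re-deriving the generator.

## Problem sizes for the shipped experiment runs

The test suite and acceptance script run the experiments at sizes chosen as
the package's desk-scale study conditions: directional experiments
(ensemble vs single forest; ratio sweep) at 40 positives / 840 negatives
(1:21) with 50-tree forests and 5-fold CV, the sweep averaged over 2
repeats and the comparison over 10 seeds; the null check at 40/80 over 10
seeds; the end-to-end run at the default 100/2,100 with 200-tree learners
and an 80/20 stratified held-out split. These sizes leave the directional
effects large relative to seed noise (the ensemble−single BAcc gap is
≈ +0.35, the ratio/BAcc Spearman ρ ≈ −0.9) while keeping any single run in
minutes on one CPU.

## Known limitations

- The domain catalog and amino-acid-index fixtures are synthetic stand-ins
  (correct shapes, arbitrary values); production use requires the curated
  63-domain list and the 24 published property scales in the same TSV
  layouts.
- The mRMR ranking consumed by IFS is computed on the full dataset (the
  original protocol); a fully nested selection-inside-CV variant would give
  slightly more conservative curves.
- GM(2,1) coefficients are descriptors, not forecasts; no claim is made
  about the grey model's predictive adequacy per column.
- Single-thread semantics are normative; parallel execution is out of scope.
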