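# Methods

## The classification problem

Nuclear receptors (NRs) are ligand-activated transcription factors grouped
into seven subfamilies (NR1 thyroid-hormone-like, NR2 HNF4-like, NR3
estrogen-like, NR4 NGFI-B-like, NR5 fushi-tarazu-F1-like, NR6 germ-cell
nuclear-factor-like, NR0 knirps-like).  `nrpred` answers two questions from
sequence alone, hierarchically: *is this protein a nuclear receptor?* and,
if so, *which subfamily does it belong to?*

## Sequence representation

Each of the 20 amino acids carries ten physicochemical scales: PC1
hydrophobicity, PC2 hydrophilicity, PC3 side-chain mass, PC4 pK1
(alpha-COOH), PC5 pK2 (NH3), PC6 isoelectric point at 25 degC, PC7 average
buried volume, PC8 molecular weight, PC9 side-chain volume, PC10 mean
polarity.  The values are embedded constants (serializable to TSV;
version-stamped `pc10-v1`).  Before use, every scale is standardized over
the 20-letter alphabet:

    z_i = (x_i - mean(x)) / sigma(x)

with the *population* sigma (divide by 20): the conversion runs over the
complete, fixed alphabet rather than a sample of it.  The conversion has
zero mean, unit spread, is idempotent, and is invariant under positive
affine rescaling of the raw scale.  A scale with zero spread is rejected
(`ZeroVarianceScale`) — it cannot carry information.

A protein of length L becomes a 10 x L matrix M, row i holding standardized
scale i evaluated at each residue.  The fixed-length descriptor is built
from lagged covariances of the rows, with mu_i the mean of row i over the
whole sequence:

* auto-covariance (AC), same scale at distance g:
  `AC(i,g) = 1/(L-g) * sum_j (M[i,j]-mu_i)(M[i,j+g]-mu_i)`
* cross-covariance (CC), two different scales, direction dependent:
  `CC(i1,i2,g) = 1/(L-g) * sum_j (M[i1,j]-mu_i1)(M[i2,j+g]-mu_i2)`

With lags g = 1..10 this gives 10x10 = 100 AC components plus 90x10 = 900
CC components (both orderings of every scale pair): a 1000-dimensional
pseudo amino acid composition.  Canonical component order is the AC block
by (scale, lag) followed by the CC block by (scale1, scale2, lag); the
order is written into every feature-matrix header so downstream consumers
never guess.  Sequences shorter than 11 residues are rejected
(`SequenceTooShort`) rather than zero-padded: with L <= max lag the largest
lag would have an empty covariance sum.  Non-canonical residue codes (B, J,
O, U, X, Z, `*`) are dropped with a warning count (imputing the
standardized mean would bias covariances toward zero across runs of
unknowns); a strict mode turns drops into errors, and inputs with more than
10% non-canonical residues are rejected outright.

## Classifier

Two RBF-kernel support-vector machines arranged hierarchically:

* **Level 1** (binary): NR vs non-NR, trained on all samples.
* **Level 2** (7-class): subfamily assignment, trained on the NR samples
  only, using libsvm's pairwise one-vs-one voting.  Subfamily labels are
  mapped to integer codes in the fixed order NR1..NR6, NR0 before fitting,
  so vote ties resolve to the lowest index in that canonical order.

Because the covariance components span orders of magnitude, each level
z-scores features using statistics fitted on its own training slice
(toggleable; on by default).  Hyperparameters (C, gamma) are selected
independently per level by a 2-D grid search maximizing mean stratified
5-fold cross-validation accuracy; the default grids are the standard
C in 2^-5..2^15, gamma in 2^-15..2^3 (steps of 2^2).  Cells are visited
with C ascending then gamma ascending and only a strictly better score
replaces the incumbent, so exact ties resolve to the smallest C, then the
smallest gamma — the smoother model.  Fold assignment is seeded and
stratified; the whole pipeline is bit-reproducible for a fixed dataset and
seed.  When the smallest class cannot fill the requested folds the fold
count drops to the class size (with a warning) down to 2; a singleton class
is an error.  No class weighting is applied by default; an optional
inverse-frequency (`balanced`) flag exists.

Prediction batches are capped at 500 sequences; per-sequence encoder
failures are reported per record without aborting the batch.  Trained
models persist as a single joblib archive carrying the property-table
version and encoder configuration; loading refuses an archive whose
encoder configuration disagrees with the running one.

## Evaluation

Overall accuracy is the exact ratio correct/total, printed as a percentage
to two decimals.  Per-class stability uses the Matthews correlation
coefficient from one-vs-rest confusion counts,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 when any marginal factor vanishes.  Per-class ACC is reported
as within-class coverage TP/(TP+FN), the form in which protein-family
studies tabulate per-class success rates; the multi-class reduction to
one-vs-rest counts is the one consistent with the four-quadrant picture of
binary outcomes.  The *overall* MCC of a multi-class report uses the
standard multi-class generalisation (scikit-learn's implementation), since
a 7-class table has no unique binary reduction.

The jackknife protocol follows the two-step convention of this literature:
(C, gamma) are fixed once by grid search on the full dataset, then each
sample in turn is predicted by both levels retrained on the remaining
samples with those hyperparameters held fixed.  This makes the jackknife
unique and deterministic.  It also means the hyperparameters have seen the
held-out sample during selection; a strict mode repeats the grid search
inside every fold for a leakage-free (but slower and no longer unique)
estimate, off by default and flagged in the report.  Stratified k-fold
evaluation is available with the same aggregation; k = n reproduces the
leave-one-out partition exactly.

### Property-impact ranking

For each scale p, the dataset is re-encoded with the nine remaining scales
(feature dimension 810), hyperparameters are re-searched, and the level's
task — binary over all samples for level 1, subfamily over NR samples for
level 2 — is evaluated by jackknife.  The impact of p is the drop of
overall accuracy relative to the ten-scale baseline; the largest drop
ranks first and exactly equal drops share a rank.

A numerical caveat discovered while validating this procedure: RBF grid
cells with near-constant kernels (gamma several orders of magnitude below
1/d for d z-scored features) can score well under stratified 5-fold CV yet
behave pathologically under leave-one-out, anti-predicting every held-out
sample.  The ranking and recovery *studies* shipped with the package
therefore use a gamma grid sized to the feature dimension
(2^-11..2^-5 for ~1000 features, C from 0.5 to 2048); the package-wide
default grids are unchanged.

## Synthetic data generator

The generator exists so that training, evaluation and ranking are fully
testable without any external dataset.  It emulates the statistical premise
that proteins of one family share similar physicochemical statistics, via
two channels:

**Composition channel** (default).  Each class draws residues from a
profile that up-weights amino acids extreme in the signal scales.  The ten
scales form three physically coherent blocks — hydropathy (PC1, PC2
anti-oriented, PC10), size (PC3, PC7, PC8, PC9), acid-base (PC4, PC5, PC6)
— and bits of the class index flip whole block directions, placing up to
eight classes at distinct corners of property space (hydrophobic/philic x
large/small x acidic/basic).  Block scores are standardized over the
alphabet before summing so no block masks another.  The class profile is
`softmax(sharpness * score)` mixed with the uniform background by weight
`separation/(1+separation)`: separation 0 is the exact null (all classes
uniform); separation 4 ("strong", mixing weight 0.8) is the documented
strong-separation setting.  Residues are drawn as a stationary sticky
chain: with probability `persistence` (default 0.5) the previous residue
repeats, otherwise a fresh profile draw.  The marginal composition is
exactly the class profile, and the geometric positional correlation gives
the covariance features an O(1), length-stable expectation proportional to
the class's property covariance — the statistic the encoder measures.
Purely i.i.d. residues were implemented first and measured: composition
alone leaves the features only an O(1/L) signal that the default length
variation (uniform on [50, 400]) swamps, and downstream accuracy stays
near chance; the sticky chain is the minimal structure that makes the
designed separation learnable.

**Arrangement channel.**  Residue composition is pleiotropic: an amino
acid extreme in one scale is extreme in correlated scales (side-chain
mass, buried volume and molecular weight correlate above 0.9 over the
alphabet), so no composition shift can make exactly *one* scale
informative.  For single-property ablation studies the generator instead
keeps the identical uniform composition in every class and varies residue
*order*: each sequence's residues are rank-matched to a latent AR(1)
series in the signal score, with the coefficient
`+/- separation/(1+separation)` alternating in sign by class.  The signal
appears directly in the signal scale's covariance features, while leakage
into another scale falls off with the squared alphabet correlation between
the scales (at most 0.41 for pK1 against any other scale, hence leak
below 0.17).

What the generator does **not** emulate: domain architecture (zinc
fingers, ligand-binding domains), motif grammar, phylogenetic relatedness,
or realistic amino-acid usage.  Passing recovery tests therefore show that
the pipeline learns composition- and arrangement-driven property
statistics at realistic lengths and sample sizes — not that it would reach
any particular accuracy on real nuclear-receptor data.

## Study sizes and defaults

The recovery study uses 100 sequences per class (non-NR plus three
subfamilies, 400 total), lengths uniform on [50, 400], separation 4, and
reports fixed-hyperparameter jackknife accuracy per level plus the
separation-0 null, which must land inside a 99% binomial band around the
majority rate.  The ranking study uses two classes of 40 sequences with an
arrangement-only pK1 signal at separation 2.  The class-size template
mirroring the original benchmark's imbalance (500 non-NR; 50/36/37/7/12/5/12
across subfamilies) is available for exercising small-class code paths
(the NR6 analog has 5 members, forcing CV fold reduction).

## Known limitations

* The two-level flow never revisits a level-1 decision: a receptor
  misjudged non-NR at level 1 receives no subfamily.
* The jackknife's fixed hyperparameters are selected on the full dataset
  (the field's convention); use strict mode for leakage-free estimates.
* Dropping non-canonical residues splices their neighbours together,
  slightly perturbing lag structure for gappy inputs.
* The generator's classes are exchangeable statistical constructs; labels
  like "NR3" carry no biological meaning there.
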