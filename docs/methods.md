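# Methods

## Problem setting

Peptide–MHC class I binding prediction underpins neoantigen discovery and
vaccine design. Pan-allele predictors take both a peptide and a
representation of the MHC molecule as input, so they can score alleles that
have no training data by exploiting similarity between MHC binding pockets.
Binding data, however, are extremely imbalanced across alleles, so model
quality varies silently from allele to allele — and therefore from patient
to patient and population to population. This package implements, end to
end at desk scale, a framework that (i) trains such a pan-allele predictor,
(ii) *measures* how its per-allele accuracy depends on what data it was
trained on, (iii) learns to *predict* that accuracy for any allele from the
training-data composition alone, and (iv) uses those predictions to decide
which alleles new experiments should target to make performance more
equitable.

## The pan-allele predictor

Each model takes the one-hot (or BLOSUM62-row) encoding of a 34-residue
MHC pseudosequence — the binding-pocket positions 31, 33, 48, … 195 of the
mature heavy chain — concatenated with the encoding of the peptide placed
in a fixed 15-mer frame (first/last four residues anchored at the ends, the
middle residues centered, `X` padding encoded as zeros). The output is a
sigmoid unit on the transformed-affinity scale

    y = 1 − log(a) / log(50 000),   a in nM,

so y = 1 at 1 nM and y = 0 at 50 µM; values outside [1, 50 000] nM are
clamped before transforming.

**Censored loss.** Records carry a measurement inequality. On the y scale
(the transform is decreasing, so nM inequalities flip) the loss per record
is

    "="  : (p − y)²
    "≥"  : 0 if p ≥ y else (p − y)²      (nM "<", e.g. elution positives at "< 100 nM")
    "≤"  : 0 if p ≤ y else (p − y)²      (nM ">", e.g. synthetic negatives at "> 20 000 nM")

Qualitative elution positives are assigned 100 nM with "<"; synthetic
negatives are proteome k-mers (lengths 8–15, equally represented) at five
times the per-allele positive count, with affinities uniform in
[20 000, 50 000] nM and ">".

**Training.** Networks have 1–3 fully connected ReLU hidden layers with
optional skip connections (a layer's input is concatenated with its output
before the next layer). Training uses RMSProp on minibatches, at most 200
epochs, early-stopped when the validation loss (mean censored MSE on an
allele-balanced 1/5 split of distinct peptide–MHC pairs) fails to improve
by 1e-4 for 20 epochs; the best-validation weights are kept. Initial
weights are a pure function of the member's `init_seed`, and the identical
initial state is reused on every retraining, so any member is
bit-reproducible. Ensembles are built by greedy forward selection on a
calibration set (add whichever candidate most lowers the censored MSE of
the ensemble mean; stop at no strict improvement) and predict the
arithmetic mean of member outputs.

The networks are implemented directly in numpy with explicit
backpropagation. This keeps the censored loss, the fixed-initialization
contract and single-thread bit-reproducibility in one small, dependency-free
training loop; float32 arithmetic is used for the (wide-input) binding
members and float64 for the small performance estimator.

## Measuring per-allele performance (leave-N-out)

Test alleles are those with ≥ 50 distinct elution positives. For each, a
series of training sets is built: set 1 excludes only the test allele's
records; each later set additionally excludes the next most similar allele
by pseudosequence distance, pulling in further neighbors until at least 10
more records have been removed (distance ties break by allele name). The
pseudosequence distance is

    d(A, B) = 1 − s(A, B) / √(s(A, A) · s(B, B)),

with s the ungapped position-wise BLOSUM62 score sum, so d(A, A) = 0.

A fresh member is trained on each set and evaluated on the test allele's
elution positives plus 99-fold proteome decoys (8–10-mers, equal lengths):
**PPV** is the fraction of true positives among the top 1 % of predictions
(bucket size ⌈0.01 N⌉; ties break by descending score then lexicographic
peptide, so PPV is deterministic). The FRANK metric — the rank-normalized
position of a known epitope among all same-protein windows, 0 best, 1
worst — is provided for epitope benchmarks; its window length range is a
parameter defaulting to 8–10.

## Predicting performance (the estimator)

Each (query allele, training summary) pair is mapped to 63 features in
five groups: the distances to the 10 nearest alleles *with data* (sorted,
padded with 1.0 when fewer exist); those neighbors' positive counts; total
positive counts in eight distance bins [0, 0.1), …, [0.7, ∞); for each of
the 34 pseudosequence positions, the total positives of training alleles
whose residue there matches the query's; and the grand total. Counts enter
as log10(1 + n) — real per-allele counts span five orders of magnitude and
raw counts would saturate the sigmoid — while distances enter raw.

The estimator is a single hidden layer of ten ReLU units with dropout
0.25 and a sigmoid output, trained with RMSProp (minibatches of 10, up to
1000 epochs, patience 100) on squared error. Evaluation uses
**PPV-balanced folds**: test alleles are sorted by mean measured PPV and
dealt round-robin to folds, all experiments of one allele staying
together; out-of-fold predictions are pooled and correlated (Pearson and
Spearman) with measured PPV, against a nearest-neighbor baseline that
predicts a query's PPV as the mean measured PPV of the most similar other
test allele.

## Data prioritization (greedy MVP selection)

With a trained estimator, the effect of collecting 4 000 new records for
candidate allele j is simulated by incrementing j's count in the summary
and re-predicting every allele's PPV. Candidate j's *impact vector* has
entry i equal to 0 when allele i is already above the median predicted
PPV, else min(after_i − current_i, median − current_i) floored at 0. The
selector repeatedly picks the candidate with the largest entry sum, then
reduces every remaining vector elementwise by the winner's (floored at 0)
so later picks complement earlier ones. The median and the per-candidate
re-predictions are computed once, before the loop — the update rule itself
contains no re-prediction step. Baselines: the k most frequent alleles
(mean frequency across population groups), and one least-data allele from
each of the k least-data supertypes. The *global PPV improvement* of a
scenario is the sum over alleles of (after − before) predicted PPV.

## Equity metrics

For a per-allele quantity c (a data count or a predicted PPV) and a
population group g with allele frequencies f, the expected value is
x_g = Σ_m c_m f_{g,m}, with f normalized to sum to one within the group
(default: pooled over all listed alleles; a per-gene mode, normalizing
within each gene and averaging, is available when the table carries a
gene column — the pooled reading is the default because the frequency
tables this mirrors sum A, B and C frequencies together). Patient-level
scores average (PPV) or sum (data coverage) the per-allele values over an
individual's six class I alleles, homozygous alleles counted per
occurrence. Group comparisons use the two-sided Mann–Whitney test.

## The synthetic universe

All components are exercised on generated data with the statistical
structure the framework assumes:

* **Pseudosequences** are sampled per cluster from a random 34-residue
  ancestor, each allele mutating positions independently (default rate
  0.05), giving tight within-cluster and large between-cluster distances.
* **Ground truth binding** gives each allele a 9 × 20 position weight
  matrix that is a *fixed random linear image of its one-hot
  pseudosequence*, so identical pseudosequences share motifs exactly and
  nearby pseudosequences have correlated motifs — the transfer structure
  pan-allele models exploit. A peptide's score is its best 9-residue
  window sum (class I binding is 9-core dominated; 8-mers skip one core
  position); scores are standardized per allele with analytic random-9-mer
  moments and squashed through a logistic onto the y scale (random
  peptides land near y ≈ 0.1, motif-sampled binders near y ≈ 0.8).
  Quantitative measurements add lognormal noise on the nM scale (default
  sd 0.5 log-units), the multiplicative error structure of BA assays.
* **Datasets**: positive peptides are sampled from each allele's motif
  (softmax at temperature 0.5, core flanked by uniform residues; length
  mix dominated by 9-mers), a configurable share carrying noisy BA values
  and the rest elution positives. Per-allele counts follow a discrete
  power law (exponent 1.5); for end-to-end studies the data alleles are
  truncated to [50, 5000] records and allocated across clusters with a
  geometrically decaying share (∝ 2^−cluster), mirroring real corpora in
  which a few HLA families hold most of the data, many alleles hold none,
  and alleles rich enough to serve as test alleles are common among data
  alleles.
* **Population frequencies** are symmetric Dirichlet draws per group.

What the generator does **not** emulate: real HLA nomenclature or
gene/locus structure, linkage between genes in genotypes, peptide-length
biases of specific assays, and any systematic (non-random) measurement
error. Passing tests therefore demonstrate that the machinery — losses,
protocols, featurization, selection — behaves as specified on data with
the assumed structure, not that any particular accuracy will be attained
on real corpora.

## Reduced-study problem sizes

The end-to-end study (`mhcequity.orchestration.run_reduced_study`) uses a
60-allele universe (5 clusters), 30 data alleles, a 15-test-allele × 4-set
LNO campaign with a single 24-unit one-layer member per training set
(one-hot encodings, RMSProp 3e-3, batch 1024, ≤ 30 epochs, patience 6),
member training capped at 150 positives per allele and PPV test sets at
100 positives (a uniformly subsampled positive set gives an unbiased PPV
estimate); summaries passed to the estimator always carry the full
counts. The estimator is evaluated with 5 PPV-balanced folds (one
training fold doubling as the early-stopping validation set) and the MVP
stage selects 5 alleles at 4 000 hypothetical records each. These sizes
were chosen so the whole study runs in minutes on one CPU while keeping
every qualitative relationship measurable.

## Numerical choices and tie-breaking

* PPV top bucket ⌈top_frac · N⌉; ties by descending score then peptide.
* Neighbor and fold ties break by allele name; FRANK rank is
  1 + #{strictly higher scores} (optimistic under ties).
* Duplicate BA measurements for one pair are averaged; a pair with both
  BA and elution records keeps the quantitative BA record; BA duplicates
  with conflicting inequalities keep "=" when present (else the
  lexicographically smallest symbol) and log a warning.
* Per-allele validation splits take floor(fraction · n_pairs) pairs, so
  one-pair alleles never lose their only training record.
* Even-length middles in the 15-mer frame are placed left-biased (the
  spare pad slot goes right); this convention is fixed and documented
  rather than inferred.
* Distance bins are half-open [lo, hi) with the last bin unbounded, so
  the eight bins partition [0, ∞) and bin totals conserve the grand total.
* Greedy ensemble selection may in principle re-add a member; an exact
  duplicate never strictly improves the mean and is therefore never added.

## Known limitations

* The binding members are small MLPs on one-hot inputs; they learn the
  synthetic bilinear ground truth well but are not tuned for real corpora
  (no hyperparameter search is included by design — architectures are
  caller-supplied configs).
* The MVP selector approximates joint additions additively (impact
  vectors are computed for single-allele additions and only updated by
  subtraction), exactly as the update rule implies; `ppv_after` for the
  selected set is, however, a genuine joint re-prediction.
* Per-allele PPV measured from ~100 positives carries binomial noise of
  roughly ±0.05, which bounds how well any estimator can correlate with
  it at this scale.
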