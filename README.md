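# mhcequity

Equitable pan-allele MHC class I binding prediction: a censored-loss
pan-MHC binding predictor, a per-allele performance estimator, and a
greedy data-prioritization algorithm, with population-level equity
metrics — all runnable end to end on a built-in synthetic allele
universe.

## Who this is for

Immunoinformaticians and ML-for-biology researchers who work with
pan-allele peptide–MHC binding models and want to (a) quantify how a
model's accuracy varies across the thousands of HLA alleles as a function
of the training data available near each allele, and (b) decide which
alleles to target with new binding experiments so that predictive
performance becomes more even across alleles, patients and populations.

## The core ideas

**Pan-allele prediction with an inequality-censored loss.** A predictor
scores a (34-residue MHC pseudosequence, 8–15-mer peptide) pair on the
transformed affinity scale `y = 1 − log(a)/log(50000)` (a in nM). Mixed
data — quantitative binding affinities ("="), qualitative elution
positives (assigned "< 100 nM") and synthetic proteome decoys
("> 20 000 nM") — train a single regression through a censored squared
error: a record contributes no loss while its inequality is satisfied.
Ensembles of deterministic, fixed-initialization networks predict the
mean of their members.

**Measuring per-allele PPV via leave-N-out (LNO).** For each test allele,
a series of training sets progressively removes the allele's own data and
then its nearest neighbors' (by the BLOSUM62 pseudosequence distance
`d = 1 − s(A,B)/√(s(A,A)s(B,B))`), at least 10 records per step. Each
trained model is scored on the test allele with 99:1 decoys; PPV is the
fraction of true binders in the top 1 % of predictions.

**Predicting PPV from data composition.** A shallow estimator (10 ReLU
units, dropout 0.25, sigmoid) maps 63 features of the (query allele,
training summary) relationship — 10 nearest-data-allele distances, their
10 counts, 8 distance-binned count totals, 34 residue-position-matched
count totals, and the grand total — to the PPV the predictor would
achieve. It is evaluated out-of-fold with PPV-balanced folds against a
nearest-neighbor baseline.

**Greedy data prioritization.** For every candidate allele, an impact
vector records how much adding 4 000 records for it would lift each
below-median allele toward the median predicted PPV. The selector
greedily picks maximal-impact alleles, discounting remaining vectors by
each winner so picks complement each other. Frequency-based and
supertype-based selections and the global PPV improvement
(Σ after − before) serve as comparators, and expected values
`x_g = Σ_m c_m f_{g,m}` aggregate any per-allele quantity over population
allele-frequency tables.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

The whole reduced study — synthetic universe, LNO campaign, estimator
cross-validation, MVP selection — in one call (a few minutes on one CPU):

```python
from mhcequity.orchestration import run_reduced_study

study = run_reduced_study(seed=1)
ev = study["evaluation"]
print(f"estimator  Pearson {ev['model_pearson']:.3f}  Spearman {ev['model_spearman']:.3f}")
print(f"NN baseline Pearson {ev['baseline_pearson']:.3f}  Spearman {ev['baseline_spearman']:.3f}")
print(f"MVP picks: {', '.join(study['mvp'].selected)}")
print(f"predicted PPV: mean {study['ppv_mean_before']:.3f} -> {study['ppv_mean_after']:.3f}, "
      f"SD {study['ppv_sd_before']:.3f} -> {study['ppv_sd_after']:.3f}")
```

prints

```
estimator  Pearson 0.927  Spearman 0.757
NN baseline Pearson 0.786  Spearman 0.639
MVP picks: SYN0049, SYN0028, SYN0033, SYN0046, SYN0016
predicted PPV: mean 0.557 -> 0.644, SD 0.145 -> 0.050
```

Reading the output: across 60 LNO experiments (15 test alleles × 4
training sets), the estimator's out-of-fold correlation with measured PPV
(Pearson 0.93) clearly beats predicting each allele's PPV from its
nearest neighbor's (0.79) — performance is predictable from training-data
composition beyond simple proximity. Simulating 4 000 new records for
each of the five greedily selected alleles raises the mean predicted PPV
across all 60 alleles (0.56 → 0.64) while shrinking its spread
(SD 0.145 → 0.050): data collection targeted at the selected alleles makes
predictions both better and more even.

The same pipeline is scriptable from the shell:

```bash
mhcequity simulate --n-alleles 60 --n-clusters 5 --seed 1 --out-dir syn/
mhcequity network syn/pseudosequences.tsv --records syn/binding_records.tsv --out-dir syn/
mhcequity run-all --seed 1 --out-dir run/
```

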