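"""Leave-N-out (LNO) protocol: PPV measurement and training labels.

For each test allele (one with enough distinct elution positives), a
series of predictor training sets is built: the first excludes only the
test allele's data; each successive set additionally excludes the next
most pseudosequence-similar allele(s), continuing until at least a
minimum number of extra records has been removed. A predictor trained on
each set is evaluated on the test allele with a 99:1 decoy test set, and
the positive predictive value (PPV) in the top 1% of predictions becomes
one training example for the downstream performance estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .binding_data import (
    BindingRecord,
    SOURCE_EL,
    assign_qualitative_labels,
    generate_synthetic_negatives,
)
from .encoders import distances_to_query
from .panmhc import BindingPredictor, NetworkConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingDataSummary:
    """Per-allele positive-record counts plus pseudosequences.

    This is the view of a predictor training set that the performance
    estimator consumes: it does not retain the records themselves, only
    how many positives each allele contributes and what the alleles look
    like.
    """

    counts: Mapping[str, int]
    pseudosequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for allele, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {allele!r}")
            if allele not in self.pseudosequences:
                raise ValueError(f"no pseudosequence for counted allele {allele!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def data_alleles(self) -> list[str]:
        """Alleles with at least one positive record, sorted by name."""
        return sorted(a for a, c in self.counts.items() if c > 0)


def summary_from_records(
    records: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str],
) -> TrainingDataSummary:
    """Summarize positive records per allele."""
    counts: dict[str, int] = {}
    for r in records:
        if r.is_positive:
            counts[r.allele] = counts.get(r.allele, 0) + 1
    pseqs = {a: pseudosequences[a] for a in counts}
    return TrainingDataSummary(counts=counts, pseudosequences=pseqs)


@dataclass
class LNOExperiment:
    """One (test allele, exclusion set, training summary, PPV) example."""

    test_allele: str
    set_index: int
    excluded_alleles: tuple[str, ...]
    training_summary: TrainingDataSummary
    measured_ppv: float | None = None

    def __post_init__(self) -> None:
        if self.test_allele not in self.excluded_alleles:
            raise ValueError("test allele must be in the excluded set")
        if self.measured_ppv is not None and not 0.0 <= self.measured_ppv <= 1.0:
            raise ValueError("measured_ppv must lie in [0, 1]")


def select_test_alleles(
    records: Sequence[BindingRecord], min_el: int = 50
) -> list[str]:
    """Alleles with at least ``min_el`` distinct elution positives."""
    distinct: dict[str, set[str]] = {}
    for r in records:
        if r.source == SOURCE_EL:
            distinct.setdefault(r.allele, set()).add(r.peptide)
    return sorted(a for a, peps in distinct.items() if len(peps) >= min_el)


def build_lno_series(
    records: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str],
    test_allele: str,
    n_sets: int = 10,
    min_excluded: int = 10,
) -> list[LNOExperiment]:
    """Nested exclusion series for one test allele.

    Set 1 removes only the test allele's records. Each following set
    removes the next most similar allele(s) by BLOSUM62 distance, pulling
    in additional neighbors until at least ``min_excluded`` extra records
    have been removed. Distance ties break by allele name. If neighbors
    run out a shorter series is returned with a warning.
    """
    alleles_with_data = sorted({r.allele for r in records})
    if test_allele not in alleles_with_data:
        raise ValueError(f"test allele {test_allele!r} has no records")
    rec_count = {a: 0 for a in alleles_with_data}
    for r in records:
        rec_count[r.allele] += 1

    neighbors = [a for a in alleles_with_data if a != test_allele]
    d = distances_to_query(
        pseudosequences[test_allele], [pseudosequences[a] for a in neighbors]
    )
    order = sorted(range(len(neighbors)), key=lambda i: (d[i], neighbors[i]))
    queue = [neighbors[i] for i in order]

    experiments: list[LNOExperiment] = []
    excluded: list[str] = [test_allele]
    for set_index in range(1, n_sets + 1):
        if set_index > 1:
            removed = 0
            added_any = False
            while queue and removed < min_excluded:
                nxt = queue.pop(0)
                excluded.append(nxt)
                removed += rec_count[nxt]
                added_any = True
            if not added_any:
                logger.warning(
                    "LNO series for %s truncated at %d sets: neighbors exhausted",
                    test_allele, set_index - 1,
                )
                break
        kept = [r for r in records if r.allele not in excluded]
        summary = summary_from_records(kept, pseudosequences)
        experiments.append(
            LNOExperiment(
                test_allele=test_allele,
                set_index=set_index,
                excluded_alleles=tuple(excluded),
                training_summary=summary,
            )
        )
    return experiments


def _negatives_pool(
    proteome: Sequence[str], n: int, lengths: Sequence[int], rng: np.random.Generator
) -> list[str]:
    """n random k-mers from the proteome, lengths equally represented."""
    lengths = sorted(lengths)
    usable = {L: [s for s in proteome if len(s) >= L] for L in lengths}
    for L, seqs in usable.items():
        if not seqs:
            raise ValueError(f"no proteome sequence long enough for {L}-mers")
    base, rem = divmod(n, len(lengths))
    out = []
    for i, L in enumerate(lengths):
        seqs = usable[L]
        for _ in range(base + (1 if i < rem else 0)):
            s = seqs[rng.integers(len(seqs))]
            start = int(rng.integers(len(s) - L + 1))
            out.append(s[start : start + L])
    return out


def measure_ppv(
    model,
    test_allele,
    positives: Sequence[str],
    proteome: Sequence[str],
    neg_ratio: int = 99,
    top_frac: float = 0.01,
    seed: int = 0,
) -> float:
    """PPV of a model on a decoy test set for one allele.

    The test set is the given positive peptides plus ``neg_ratio`` times
    as many proteome k-mers (lengths 8–10 equally represented). All are
    scored; PPV is the fraction of positives among the top
    ``ceil(top_frac * N)`` predictions. Ties break by descending score
    then lexicographic peptide, deterministically.

    ``model`` is anything with ``score_peptides(allele, peptides)``; a
    bare callable ``peptides -> scores`` is also accepted.
    """
    n = len(positives)
    if n == 0:
        raise ValueError("no positive peptides")
    rng = np.random.default_rng(seed)
    negatives = _negatives_pool(proteome, neg_ratio * n, range(8, 11), rng)
    peptides = list(positives) + negatives
    is_pos = np.zeros(len(peptides), dtype=bool)
    is_pos[:n] = True

    if callable(model) and not hasattr(model, "score_peptides"):
        scores = np.asarray(model(peptides), dtype=np.float64)
    else:
        scores = np.asarray(model.score_peptides(test_allele, peptides), dtype=np.float64)

    m = math.ceil(top_frac * len(peptides))
    # stable order: descending score, then peptide lexicographic
    order = sorted(range(len(peptides)), key=lambda i: (-scores[i], peptides[i]))
    top = order[:m]
    return float(np.sum(is_pos[top]) / m)


def frank_score(
    model,
    allele,
    epitope: str,
    protein: str,
    lengths: Sequence[int] = tuple(range(8, 11)),
) -> float:
    """Rank-normalized position of an epitope among same-protein peptides.

    All distinct windows of the given lengths are scored; the epitope's
    FRANK is (rank - 1)/(N - 1) with rank 1 for the top-scoring peptide,
    so 0 is best and 1 worst. The epitope's rank uses the optimistic
    convention 1 + #{peptides scoring strictly higher}.
    """
    if len(epitope) not in lengths or epitope not in protein:
        raise ValueError("epitope must occur in the protein with an allowed length")
    windows = sorted(
        {protein[i : i + L] for L in lengths for i in range(len(protein) - L + 1)}
    )
    if callable(model) and not hasattr(model, "score_peptides"):
        scores = np.asarray(model(windows), dtype=np.float64)
    else:
        scores = np.asarray(model.score_peptides(allele, windows), dtype=np.float64)
    e_score = scores[windows.index(epitope)]
    rank = 1 + int(np.sum(scores > e_score))
    return float((rank - 1) / (len(windows) - 1))


# ---------------------------------------------------------------------------
# reduced campaign driver


def run_lno_campaign(
    records: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str],
    proteome: Sequence[str],
    member_config: NetworkConfig,
    n_test_alleles: int | None = None,
    n_sets: int = 10,
    min_el: int = 50,
    min_excluded: int = 10,
    max_positives_per_allele: int | None = None,
    max_test_positives: int | None = None,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> list[LNOExperiment]:
    """Run a (possibly reduced) LNO campaign end to end.

    Selects test alleles (at least ``min_el`` distinct elution
    positives; if fewer than ``n_test_alleles`` qualify the threshold
    falls back to the n-th largest count, with a warning), builds each
    exclusion series, trains one predictor member per training set and
    measures its PPV on the test allele. ``max_positives_per_allele``
    caps the records actually used to train each member (the summaries
    consumed by the performance estimator always reflect the full
    counts); ``max_test_positives`` caps the elution positives entering
    each PPV test set (a PPV estimated on a random subsample of
    positives is an unbiased estimate of the full-set PPV).
    """
    rng = np.random.default_rng(seed)
    test_alleles = select_test_alleles(records, min_el)
    if n_test_alleles is not None and len(test_alleles) > n_test_alleles:
        # keep those with the most distinct elution positives
        distinct: dict[str, set[str]] = {}
        for r in records:
            if r.source == SOURCE_EL:
                distinct.setdefault(r.allele, set()).add(r.peptide)
        test_alleles = sorted(
            test_alleles, key=lambda a: (-len(distinct[a]), a)
        )[:n_test_alleles]
        test_alleles.sort()
    elif n_test_alleles is not None and len(test_alleles) < n_test_alleles:
        distinct = {}
        for r in records:
            if r.source == SOURCE_EL:
                distinct.setdefault(r.allele, set()).add(r.peptide)
        ranked = sorted(distinct, key=lambda a: (-len(distinct[a]), a))
        test_alleles = sorted(ranked[:n_test_alleles])
        logger.warning(
            "only %d alleles reach %d distinct elution records; "
            "falling back to the %d best-covered alleles",
            sum(1 for a in ranked if len(distinct[a]) >= min_el), min_el, n_test_alleles,
        )

    el_peptides: dict[str, list[str]] = {}
    for r in records:
        if r.source == SOURCE_EL:
            el_peptides.setdefault(r.allele, []).append(r.peptide)

    experiments: list[LNOExperiment] = []
    for allele in test_alleles:
        series = build_lno_series(records, pseudosequences, allele,
                                  n_sets=n_sets, min_excluded=min_excluded)
        for exp in series:
            train_pos = [
                r for r in records if r.allele not in exp.excluded_alleles
            ]
            if max_positives_per_allele is not None:
                capped: list[BindingRecord] = []
                by_a: dict[str, int] = {}
                for r in train_pos:
                    k = by_a.get(r.allele, 0)
                    if k < max_positives_per_allele:
                        capped.append(r)
                        by_a[r.allele] = k + 1
                train_pos = capped
            train_pos = assign_qualitative_labels(train_pos)
            neg_seed = int(rng.integers(2**31))
            negatives = generate_synthetic_negatives(
                train_pos, proteome, ratio=5, seed=neg_seed
            )
            all_records = train_pos + negatives
            predictor = BindingPredictor(member_config, pseudosequences)
            predictor.fit(all_records, split_seed=neg_seed)
            test_pos = sorted(set(el_peptides[allele]))
            if max_test_positives is not None and len(test_pos) > max_test_positives:
                keep = rng.choice(len(test_pos), size=max_test_positives, replace=False)
                test_pos = [test_pos[i] for i in sorted(keep)]
            ppv = measure_ppv(
                predictor,
                pseudosequences[allele],
                test_pos,
                proteome,
                seed=int(rng.integers(2**31)),
            )
            exp.measured_ppv = ppv
            experiments.append(exp)
            if progress:
                progress(f"{allele} set {exp.set_index}: PPV={ppv:.3f}")
    return experiments


def load_campaign_manifest(
    path,
    records: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str],
) -> list[LNOExperiment]:
    """Rebuild LNO experiments from a written manifest plus the records.

    The manifest stores exclusion sets and measured PPVs; training
    summaries are reconstructed deterministically from the record list.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        excluded = tuple(str(row.excluded_alleles).split(";"))
        kept = [r for r in records if r.allele not in excluded]
        out.append(
            LNOExperiment(
                test_allele=str(row.test_allele),
                set_index=int(row.set_index),
                excluded_alleles=excluded,
                training_summary=summary_from_records(kept, pseudosequences),
                measured_ppv=float(row.measured_ppv),
            )
        )
    return out


def write_campaign_manifest(experiments: Sequence[LNOExperiment], path) -> None:
    """Write the campaign as TSV: test allele, set, exclusions, size, PPV."""
    import pandas as pd

    rows = [
        {
            "test_allele": e.test_allele,
            "set_index": e.set_index,
            "excluded_alleles": ";".join(e.excluded_alleles),
            "n_train_records": e.training_summary.total,
            "measured_ppv": e.measured_ppv,
        }
        for e in experiments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
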