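"""Greedy prioritization of alleles for new data collection.

For every candidate allele j the selector asks the performance estimator
what each allele i's predicted PPV would be if 4,000 new binding records
were collected for j, and condenses the answer into an impact vector:
entry i is zero when allele i already performs above the median
predicted PPV, and otherwise the predicted improvement for i, capped by
i's gap to the median. The candidate with the largest total impact is
picked; every remaining impact vector is then reduced elementwise by the
winner's vector (floored at zero) so subsequent picks are complementary.
Frequency-based and supertype-based selections are provided as
baselines, along with the global PPV improvement metric (sum over
alleles of after-minus-before predicted PPV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lno_protocol import TrainingDataSummary
from .perf_estimator import featurize

logger = logging.getLogger(__name__)


@dataclass
class ImpactVector:
    """Capped per-allele PPV improvements from adding data to one candidate."""

    candidate: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        for a, v in self.entries.items():
            if v < 0:
                raise ValueError(f"negative impact entry for {a!r}")

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))


@dataclass
class MVPResult:
    """Ordered greedy selection with per-iteration scores."""

    selected: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    ppv_before: dict[str, float] = field(default_factory=dict)
    ppv_after: dict[str, float] = field(default_factory=dict)


def simulate_data_addition(
    summary: TrainingDataSummary,
    allele: str,
    n_added: int = 4000,
    pseudosequences: Mapping[str, str] | None = None,
) -> TrainingDataSummary:
    """Copy of the summary with ``n_added`` hypothetical records for one allele."""
    pseqs = dict(summary.pseudosequences)
    if allele not in pseqs:
        if pseudosequences is None or allele not in pseudosequences:
            raise ValueError(f"no pseudosequence known for {allele!r}")
        pseqs[allele] = pseudosequences[allele]
    counts = dict(summary.counts)
    counts[allele] = counts.get(allele, 0) + n_added
    return TrainingDataSummary(counts=counts, pseudosequences=pseqs)


def compute_impact_vector(
    candidate: str,
    current_ppv: Mapping[str, float],
    after_ppv: Mapping[str, float],
    median_ppv: float,
) -> ImpactVector:
    """Impact of adding data to ``candidate`` on every allele's PPV.

    Entry i = 0 if current PPV of i exceeds the median; otherwise
    min(after_i - current_i, median - current_i), floored at 0.
    """
    if set(current_ppv) != set(after_ppv):
        raise ValueError("current and after PPV maps must share key sets")
    entries: dict[str, float] = {}
    for a in current_ppv:
        cur = current_ppv[a]
        if cur > median_ppv:
            entries[a] = 0.0
        else:
            entries[a] = max(0.0, min(after_ppv[a] - cur, median_ppv - cur))
    return ImpactVector(candidate=candidate, entries=entries)


def greedy_mvp(impact_vectors: Mapping[str, ImpactVector], k: int) -> MVPResult:
    """Greedy selection of up to ``k`` alleles by total impact.

    After each pick m, every remaining vector v_j becomes
    max(v_j - v_m, 0) elementwise. Stops early when all remaining total
    scores are zero. Total-score ties break by allele name.
    """
    if not impact_vectors:
        raise ValueError("no impact vectors")
    if k < 1:
        raise ValueError("k must be at least 1")
    alleles = sorted(set().union(*(v.entries for v in impact_vectors.values())))
    vecs = {
        j: np.array([iv.entries.get(a, 0.0) for a in alleles])
        for j, iv in impact_vectors.items()
    }
    remaining = sorted(vecs)
    result = MVPResult()
    for _ in range(min(k, len(remaining))):
        totals = {j: float(vecs[j].sum()) for j in remaining}
        best = min(remaining, key=lambda j: (-totals[j], j))
        if totals[best] <= 0.0:
            break
        result.selected.append(best)
        result.scores.append(totals[best])
        v_m = vecs[best]
        remaining.remove(best)
        for j in remaining:
            vecs[j] = np.maximum(vecs[j] - v_m, 0.0)
    return result


def global_ppv_improvement(
    before: Mapping[str, float], after: Mapping[str, float]
) -> float:
    """Sum over alleles of (after - before) predicted PPV."""
    if set(before) != set(after):
        raise ValueError("before and after maps must share key sets")
    return float(sum(after[a] - before[a] for a in before))


def frequency_baseline(freq_table, k: int = 20) -> list[str]:
    """Top-k alleles by mean frequency across population groups.

    ``freq_table`` is a DataFrame with columns group/allele/frequency.
    Ties break by allele name.
    """
    if len(freq_table) == 0:
        raise ValueError("empty frequency table")
    mean_freq = freq_table.groupby("allele")["frequency"].mean()
    ranked = sorted(mean_freq.index, key=lambda a: (-mean_freq[a], a))
    return ranked[:k]


def supertype_baseline(
    supertype_map: Mapping[str, str],
    summary: TrainingDataSummary,
    k: int = 20,
) -> list[str]:
    """One least-data allele from each of the k least-data supertypes."""
    totals: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for allele, st in supertype_map.items():
        members.setdefault(st, []).append(allele)
        totals[st] = totals.get(st, 0) + summary.counts.get(allele, 0)
    supertypes = sorted(totals, key=lambda s: (totals[s], s))
    if len(supertypes) < k:
        logger.warning("only %d supertypes available, requested %d", len(supertypes), k)
    chosen = []
    for st in supertypes[:k]:
        allele = min(members[st], key=lambda a: (summary.counts.get(a, 0), a))
        chosen.append(allele)
    return chosen


# ---------------------------------------------------------------------------
# end-to-end selection with a trained performance estimator


def predict_ppv_map(
    perf_model,
    pseudosequences: Mapping[str, str],
    summary: TrainingDataSummary,
    alleles: Sequence[str] | None = None,
) -> dict[str, float]:
    """Predicted PPV for every allele under one training summary."""
    if alleles is None:
        alleles = sorted(pseudosequences)
    X = np.stack([featurize(pseudosequences[a], summary) for a in alleles])
    pred = perf_model.predict(X)
    return dict(zip(alleles, (float(p) for p in pred)))


def select_mvp_alleles(
    perf_model,
    pseudosequences: Mapping[str, str],
    summary: TrainingDataSummary,
    k: int = 20,
    n_added: int = 4000,
    candidates: Sequence[str] | None = None,
) -> MVPResult:
    """Full greedy selection driven by the performance estimator.

    Computes current predicted PPVs and their median once, one
    hypothetical-addition re-prediction per candidate, the impact
    vectors, and the greedy pick sequence. ``ppv_after`` in the result
    is the re-prediction after adding ``n_added`` records to every
    selected allele jointly.
    """
    alleles = sorted(pseudosequences)
    if candidates is None:
        candidates = alleles
    current = predict_ppv_map(perf_model, pseudosequences, summary, alleles)
    median = float(np.median(list(current.values())))
    vectors: dict[str, ImpactVector] = {}
    for j in candidates:
        after_summary = simulate_data_addition(summary, j, n_added, pseudosequences)
        after = predict_ppv_map(perf_model, pseudosequences, after_summary, alleles)
        vectors[j] = compute_impact_vector(j, current, after, median)
    result = greedy_mvp(vectors, k)
    result.ppv_before = current
    enriched = summary
    for a in result.selected:
        enriched = simulate_data_addition(enriched, a, n_added, pseudosequences)
    result.ppv_after = predict_ppv_map(perf_model, pseudosequences, enriched, alleles)
    return result
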