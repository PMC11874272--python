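"""Population- and patient-level aggregation of per-allele quantities.

Given any per-allele value c_m (a data count, a predicted PPV), the
expected value for a population group g is x_g = sum_m c_m * f_{g,m}
with f the group's allele frequencies normalized to sum to one. Patient
scores average (or sum) the per-allele values over an individual's six
class I alleles, counting homozygous alleles per occurrence. Group
comparisons use the two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FREQUENCY_COLUMNS = ["group", "allele", "frequency"]


@dataclass(frozen=True)
class Genotype:
    """Six class I alleles (two each for three genes) of one individual."""

    individual: str
    alleles: tuple[str, str, str, str, str, str]
    group: str | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) != 6:
            raise ValueError("a genotype carries exactly six alleles")


def _group_frequencies(
    table: pd.DataFrame, group: str, mode: str = "pooled"
) -> pd.Series:
    sub = table[table["group"] == group]
    if sub.empty:
        raise KeyError(f"unknown group {group!r}")
    if mode == "pooled":
        f = sub.set_index("allele")["frequency"].astype(float)
        return f / f.sum()
    if mode == "per_gene":
        if "gene" not in sub.columns:
            raise ValueError("per_gene normalization requires a 'gene' column")
        parts = []
        n_genes = sub["gene"].nunique()
        for _, g in sub.groupby("gene"):
            f = g.set_index("allele")["frequency"].astype(float)
            parts.append(f / f.sum() / n_genes)
        return pd.concat(parts)
    raise ValueError(f"unknown normalization mode {mode!r}")


def expected_group_value(
    values: Mapping[str, float],
    table: pd.DataFrame,
    group: str,
    mode: str = "pooled",
) -> float:
    """x_g = sum_m values[m] * f_{g,m} with normalized group frequencies.

    ``mode="pooled"`` (default) rescales the group's frequencies over all
    listed alleles to sum to one; ``mode="per_gene"`` normalizes within
    each gene and averages across genes (requires a ``gene`` column).
    Alleles missing from ``values`` contribute 0 with a warning.
    """
    f = _group_frequencies(table, group, mode)
    missing = [a for a in f.index if a not in values]
    if missing:
        logger.warning("%d alleles in group %r have no value; treated as 0",
                       len(missing), group)
    return float(sum(f[a] * values.get(a, 0.0) for a in f.index))


def patient_score(genotype: Genotype, per_allele_values: Mapping[str, float]) -> float:
    """Mean of the per-allele values over the six alleles (duplicates count)."""
    missing = [a for a in genotype.alleles if a not in per_allele_values]
    if missing:
        raise KeyError(f"no value for allele(s) {sorted(set(missing))}")
    return float(np.mean([per_allele_values[a] for a in genotype.alleles]))


def patient_data_coverage(genotype: Genotype, counts: Mapping[str, float]) -> float:
    """Sum of per-allele data counts over the six alleles."""
    missing = [a for a in genotype.alleles if a not in counts]
    if missing:
        raise KeyError(f"no count for allele(s) {sorted(set(missing))}")
    return float(sum(counts[a] for a in genotype.alleles))


def group_comparison_report(
    scores: Mapping[str, float], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests between groups of individuals.

    Returns one row per group pair: the rank-sum U statistic, the
    two-sided p-value, and both group medians. Groups with fewer than
    two members are skipped with a warning.
    """
    by_group: dict[str, list[float]] = {}
    for ind, s in scores.items():
        g = groups.get(ind)
        if g is None:
            continue
        by_group.setdefault(g, []).append(float(s))
    usable = {g: v for g, v in by_group.items() if len(v) >= 2}
    for g in set(by_group) - set(usable):
        logger.warning("group %r has fewer than 2 members; skipped", g)
    if len(usable) < 2:
        raise ValueError("need at least two groups with at least two members")
    names = sorted(usable)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            u, p = stats.mannwhitneyu(usable[g1], usable[g2], alternative="two-sided")
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "statistic": float(u),
                    "p_value": float(p),
                    "median1": float(np.median(usable[g1])),
                    "median2": float(np.median(usable[g2])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_frequency_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FREQUENCY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns {sorted(missing)}")
    if (df["frequency"] < 0).any():
        raise ValueError("negative frequencies")
    return df


def write_frequency_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> list[Genotype]:
    """Read genotypes: individual, group, then six allele columns."""
    df = pd.read_csv(path, sep="\t")
    allele_cols = [c for c in df.columns if c not in ("individual", "group")]
    if len(allele_cols) != 6:
        raise ValueError(f"expected six allele columns, got {allele_cols}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            Genotype(
                individual=str(d["individual"]),
                alleles=tuple(str(d[c]) for c in allele_cols),
                group=str(d["group"]) if "group" in d else None,
            )
        )
    return out
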