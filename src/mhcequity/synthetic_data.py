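"""Synthetic allele universes, binding ground truth, and datasets.

Real pan-allele binding data have three structural properties this
package's machinery depends on: pseudosequences fall into clusters of
similar alleles, binding motifs vary smoothly with pseudosequence
similarity (so models can transfer across alleles), and per-allele data
counts are extremely imbalanced. The generators here reproduce those
properties at desk scale so every downstream component can be exercised
and tested without external downloads.

The ground-truth binding function ("oracle") gives each allele a 9 x 20
position weight matrix that is a fixed random linear function of its
one-hot pseudosequence encoding: identical pseudosequences get identical
motifs, and nearby pseudosequences get correlated motifs. A peptide's
score is the best 9-residue window sum (class I binding is dominated by
a 9-residue core); scores are mapped through a logistic squash to the
unit-interval affinity scale and then to nM, with optional lognormal
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding_data import (
    BindingRecord,
    QUALITATIVE_POSITIVE_NM,
    SOURCE_BA,
    SOURCE_EL,
    inverse_transform,
)
from .encoders import AMINO_ACIDS, PSEUDOSEQUENCE_LENGTH, _AA_INDEX

CORE_LENGTH = 9

# Peptide length mix for sampled positives: class I ligands are mostly
# 9-mers with a tail of longer peptides.
LENGTH_WEIGHTS = {8: 0.10, 9: 0.45, 10: 0.20, 11: 0.10, 12: 0.05, 13: 0.04, 14: 0.03, 15: 0.03}


@dataclass(frozen=True)
class SyntheticUniverse:
    """A set of named alleles with pseudosequences and cluster labels."""

    alleles: tuple[str, ...]
    pseudosequences: Mapping[str, str]
    cluster_id: Mapping[str, int]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("allele names must be unique")
        for a in self.alleles:
            ps = self.pseudosequences[a]
            if len(ps) != PSEUDOSEQUENCE_LENGTH or set(ps) - set(AMINO_ACIDS):
                raise ValueError(f"invalid pseudosequence for {a!r}")


def generate_allele_universe(
    n_alleles: int,
    n_clusters: int,
    mutation_rate: float,
    seed: int,
) -> SyntheticUniverse:
    """Sample a clustered universe of 34-residue pseudosequences.

    One random ancestor pseudosequence is drawn per cluster; each allele
    copies its cluster's ancestor and mutates every position
    independently with probability ``mutation_rate`` (to a different
    residue). Alleles are assigned to clusters round-robin so no cluster
    is empty.
    """
    if n_alleles < 1 or n_clusters < 1:
        raise ValueError("n_alleles and n_clusters must be positive")
    if n_clusters > n_alleles:
        raise ValueError("n_clusters cannot exceed n_alleles")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    ancestors = [
        "".join(rng.choice(aa, size=PSEUDOSEQUENCE_LENGTH)) for _ in range(n_clusters)
    ]
    alleles = tuple(f"SYN{i:04d}" for i in range(n_alleles))
    pseudos: dict[str, str] = {}
    clusters: dict[str, int] = {}
    for i, name in enumerate(alleles):
        c = i % n_clusters
        seq = list(ancestors[c])
        for p in range(PSEUDOSEQUENCE_LENGTH):
            if rng.random() < mutation_rate:
                choices = [x for x in AMINO_ACIDS if x != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
        pseudos[name] = "".join(seq)
        clusters[name] = c
    return SyntheticUniverse(
        alleles=alleles, pseudosequences=pseudos, cluster_id=clusters, seed=seed
    )


def _onehot_pseudo(residues: str) -> np.ndarray:
    v = np.zeros(PSEUDOSEQUENCE_LENGTH * 20)
    for i, ch in enumerate(residues):
        v[i * 20 + _AA_INDEX[ch]] = 1.0
    return v


@dataclass
class BindingOracle:
    """Deterministic ground-truth binding function over a universe.

    ``motifs[allele]`` is a 9 x 20 position weight matrix, a fixed
    linear image of the allele's one-hot pseudosequence; entries are
    approximately standard normal. ``score`` is the best 9-window motif
    sum; ``transformed_affinity`` squashes the allele-standardized score
    onto [0, 1] (the same scale the predictor is trained on).
    """

    universe: SyntheticUniverse
    noise_sd: float
    seed: int
    motifs: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _norms: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)

    # logistic squash placing random 9-mers near 0.1 and motif-matched
    # peptides near 0.8 on the transformed-affinity scale
    SQUASH_CENTER = 2.2
    SQUASH_SLOPE = 0.9

    def __post_init__(self) -> None:
        if not self.universe.alleles:
            raise ValueError("universe is empty")
        rng = np.random.default_rng(self.seed)
        # fixed random linear map: (34*20) -> (9*20); scaling chosen so
        # motif entries have unit variance (34 active inputs per allele)
        T = rng.normal(0.0, 1.0 / np.sqrt(PSEUDOSEQUENCE_LENGTH),
                       size=(CORE_LENGTH * 20, PSEUDOSEQUENCE_LENGTH * 20))
        for a in self.universe.alleles:
            m = (T @ _onehot_pseudo(self.universe.pseudosequences[a])).reshape(
                CORE_LENGTH, 20
            )
            self.motifs[a] = m
            # analytic mean/sd of a random 9-mer's score under this motif
            mu = float(m.mean(axis=1).sum())
            var = float((m.var(axis=1)).sum())
            self._norms[a] = (mu, np.sqrt(max(var, 1e-12)))

    def score(self, allele: str, peptide: str) -> float:
        """Raw motif score: best 9-residue window sum."""
        m = self.motifs[allele]
        idx = np.array([_AA_INDEX[c] for c in peptide])
        if len(idx) == CORE_LENGTH - 1:
            # 8-mers: best alignment skipping one core position
            best = -np.inf
            for skip in range(CORE_LENGTH):
                pos = [p for p in range(CORE_LENGTH) if p != skip]
                best = max(best, float(m[pos, idx].sum()))
            return best
        if len(idx) < CORE_LENGTH - 1:
            raise ValueError("peptide shorter than 8 residues")
        best = -np.inf
        for start in range(len(idx) - CORE_LENGTH + 1):
            w = idx[start : start + CORE_LENGTH]
            best = max(best, float(m[np.arange(CORE_LENGTH), w].sum()))
        return best

    def zscore(self, allele: str, peptide: str) -> float:
        mu, sd = self._norms[allele]
        return (self.score(allele, peptide) - mu) / sd

    def transformed_affinity(self, allele: str, peptide: str) -> float:
        """Noise-free ground-truth affinity on the [0, 1] scale."""
        z = self.zscore(allele, peptide)
        return float(1.0 / (1.0 + np.exp(-self.SQUASH_SLOPE * (z - self.SQUASH_CENTER))))

    def affinity_nm(self, allele: str, peptide: str,
                    rng: np.random.Generator | None = None) -> float:
        """Ground-truth affinity in nM with lognormal measurement noise."""
        nm = inverse_transform(self.transformed_affinity(allele, peptide))
        if self.noise_sd > 0 and rng is not None:
            nm *= float(np.exp(rng.normal(0.0, self.noise_sd)))
        return float(min(max(nm, 1.0), 50_000.0))

    def sample_binder(self, allele: str, length: int, rng: np.random.Generator,
                      temperature: float = 0.5) -> str:
        """Sample a motif-consistent peptide of the given length.

        Core residues are drawn position-wise from softmax(motif/T);
        residues outside the 9-core are uniform.
        """
        m = self.motifs[allele]
        core = []
        for p in range(CORE_LENGTH):
            w = np.exp((m[p] - m[p].max()) / temperature)
            core.append(AMINO_ACIDS[rng.choice(20, p=w / w.sum())])
        extra = length - CORE_LENGTH
        if extra < 0:
            # 8-mers: drop one core position uniformly
            drop = int(rng.integers(CORE_LENGTH))
            return "".join(core[:drop] + core[drop + 1 :])
        flank = [AMINO_ACIDS[rng.integers(20)] for _ in range(extra)]
        cut = int(rng.integers(extra + 1))
        return "".join(flank[:cut] + core + flank[cut:])


def make_binding_oracle(
    universe: SyntheticUniverse, noise_sd: float = 0.5, seed: int = 0
) -> BindingOracle:
    """Construct the ground-truth binding function for a universe."""
    return BindingOracle(universe=universe, noise_sd=noise_sd, seed=seed)


def sample_binding_dataset(
    oracle: BindingOracle,
    counts: Mapping[str, int],
    ba_fraction: float = 0.2,
    seed: int = 0,
) -> list[BindingRecord]:
    """Sample positive binding records per allele.

    For each allele, ``counts[allele]`` distinct positive peptides are
    drawn from the allele's motif; a ``ba_fraction`` share carry noisy
    quantitative nM values (source BA, inequality "="), the rest are
    qualitative elution positives (100 nM, "<").
    """
    if not 0.0 <= ba_fraction <= 1.0:
        raise ValueError("ba_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = np.array(sorted(LENGTH_WEIGHTS))
    weights = np.array([LENGTH_WEIGHTS[L] for L in lengths])
    weights = weights / weights.sum()
    out: list[BindingRecord] = []
    for allele in sorted(counts):
        n = counts[allele]
        if n < 0:
            raise ValueError(f"negative count for {allele!r}")
        if n == 0:
            continue
        if allele not in oracle.motifs:
            raise KeyError(f"allele {allele!r} not in oracle")
        seen: set[str] = set()
        peptides: list[str] = []
        while len(peptides) < n:
            L = int(rng.choice(lengths, p=weights))
            pep = oracle.sample_binder(allele, L, rng)
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
        n_ba = int(round(ba_fraction * n))
        for i, pep in enumerate(peptides):
            if i < n_ba:
                out.append(
                    BindingRecord(
                        allele=allele,
                        peptide=pep,
                        value_nM=oracle.affinity_nm(allele, pep, rng),
                        inequality="=",
                        source=SOURCE_BA,
                    )
                )
            else:
                out.append(
                    BindingRecord(
                        allele=allele,
                        peptide=pep,
                        value_nM=QUALITATIVE_POSITIVE_NM,
                        inequality="<",
                        source=SOURCE_EL,
                    )
                )
    return out


def allocate_data_alleles(
    universe: SyntheticUniverse, n_data: int, decay: float = 0.5
) -> list[str]:
    """Choose which alleles carry binding data, skewed across clusters.

    Cluster c receives a share of the data alleles proportional to
    ``decay**c`` (at least one where the rounded share is positive), so
    some clusters are densely covered and others nearly empty — the
    coverage skew real MHC binding corpora show across HLA gene
    families. Within a cluster, the lowest-index alleles are chosen.
    """
    if not 1 <= n_data <= len(universe.alleles):
        raise ValueError("n_data must be in [1, n_alleles]")
    clusters = sorted(set(universe.cluster_id.values()))
    shares = np.array([decay**c for c in clusters], dtype=np.float64)
    shares /= shares.sum()
    n_per = np.maximum(1, np.round(shares * n_data).astype(int))
    by_cluster = {
        c: [a for a in universe.alleles if universe.cluster_id[a] == c] for c in clusters
    }
    chosen: list[str] = []
    for c in clusters:
        chosen.extend(by_cluster[c][: n_per[c]])
    return chosen[:n_data]


def sample_power_law_counts(
    alleles: Sequence[str],
    exponent: float = 1.5,
    max_count: int = 5000,
    min_count: int = 1,
    seed: int = 0,
) -> dict[str, int]:
    """Discrete power-law counts per allele, truncated to [min, max].

    P(k) proportional to k^-exponent on [min_count, max_count]; mimics
    the orders-of-magnitude spread of real per-allele data at desk
    scale.
    """
    rng = np.random.default_rng(seed)
    ks = np.arange(min_count, max_count + 1, dtype=np.float64)
    p = ks**-exponent
    p /= p.sum()
    draws = rng.choice(ks.astype(int), size=len(alleles), p=p)
    return {a: int(k) for a, k in zip(sorted(alleles), draws)}


def sample_proteome(
    n_proteins: int = 50, length: int = 400, seed: int = 0
) -> list[str]:
    """Random background protein sequences for decoy sampling."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(aa, size=length)) for _ in range(n_proteins)]


def sample_population_frequencies(
    universe: SyntheticUniverse,
    n_groups: int,
    concentration: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet allele-frequency tables for ``n_groups`` populations.

    Each group's frequency vector over all alleles is a symmetric
    Dirichlet(concentration) draw; rows per group sum to 1.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be at least 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        f = rng.dirichlet(np.full(len(universe.alleles), concentration))
        f = f / f.sum()
        for a, x in zip(universe.alleles, f):
            rows.append({"group": f"G{g + 1:02d}", "allele": a, "frequency": float(x)})
    return pd.DataFrame(rows)


def gini_coefficient(values: Sequence[float]) -> float:
    """Gini inequality coefficient of a nonnegative sample."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    if x.sum() == 0:
        return 0.0
    n = len(x)
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)
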