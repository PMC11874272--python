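"""Peptide–MHC binding records: data model, transforms, I/O.

A record ties one peptide (8–15 residues) to one MHC allele with a
measurement in nM, a measurement inequality ("<", "=", ">") and a source
label (quantitative BA assay, single-allelic elution positive, or
synthetic negative). Affinities are mapped to the unit interval via the
standard log transform y = 1 - log(a)/log(50000), so 1 nM -> 1 and
50000 nM -> 0; because the transform is decreasing, an inequality on nM
flips direction on y.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .encoders import AMINO_ACIDS

logger = logging.getLogger(__name__)

MAX_NM = 50_000.0
LOG_MAX_NM = math.log(MAX_NM)

SOURCE_BA = "BA"
SOURCE_EL = "EL-SA"
SOURCE_NEG = "SYNTH-NEG"
_SOURCES = (SOURCE_BA, SOURCE_EL, SOURCE_NEG)
_INEQUALITIES = ("<", "=", ">")

#: Qualitative elution positives are assigned this affinity with "<".
QUALITATIVE_POSITIVE_NM = 100.0

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class BindingRecord:
    """One peptide–MHC measurement."""

    allele: str
    peptide: str
    value_nM: float
    inequality: str
    source: str

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 15:
            raise ValueError(f"peptide length {len(self.peptide)} outside [8, 15]")
        if self.value_nM <= 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if self.inequality not in _INEQUALITIES:
            raise ValueError(f"inequality must be one of {_INEQUALITIES}")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")

    @property
    def is_positive(self) -> bool:
        return self.source in (SOURCE_BA, SOURCE_EL)


@dataclass(frozen=True)
class TransformedLabel:
    """Regression target on [0, 1] with the y-space inequality direction."""

    y: float
    inequality_on_y: str  # one of ">=", "=", "<="


def transform_affinity(value_nM: float) -> float:
    """Map an affinity in nM to [0, 1] via 1 - log(a)/log(50000).

    Values outside [1, 50000] nM are clamped; non-positive values raise.
    """
    if value_nM <= 0:
        raise ValueError(f"affinity must be positive, got {value_nM}")
    v = min(max(value_nM, 1.0), MAX_NM)
    return 1.0 - math.log(v) / LOG_MAX_NM


def inverse_transform(y: float) -> float:
    """Map a transformed label back to nM: exp((1 - y) * log(50000))."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"transformed label must be in [0, 1], got {y}")
    return math.exp((1.0 - y) * LOG_MAX_NM)


_FLIP = {"<": ">=", "=": "=", ">": "<="}


def transformed_label(record: BindingRecord) -> TransformedLabel:
    """Transformed target for a record; nM inequality flipped onto y."""
    return TransformedLabel(
        y=transform_affinity(record.value_nM),
        inequality_on_y=_FLIP[record.inequality],
    )


def assign_qualitative_labels(records: Iterable[BindingRecord]) -> list[BindingRecord]:
    """Give every elution positive the standard quantitative stand-in.

    Elution positives carry no affinity; they are assigned 100 nM with
    inequality "<" (the model should score them stronger than 100 nM).
    BA and synthetic-negative records pass through untouched.
    """
    out = []
    for r in records:
        if r.source == SOURCE_EL:
            out.append(replace(r, value_nM=QUALITATIVE_POSITIVE_NM, inequality="<"))
        else:
            out.append(r)
    return out


def deduplicate(records: Sequence[BindingRecord]) -> list[BindingRecord]:
    """Collapse each (allele, peptide) pair to a single record.

    Multiple quantitative BA values for one pair are replaced by their
    arithmetic mean. When a pair has both BA and qualitative records the
    quantitative BA record wins. BA duplicates with differing
    inequalities keep "=" if present, else the lexicographically smallest
    symbol; the conflict is logged.
    """
    groups: dict[tuple[str, str], list[BindingRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.allele, r.peptide)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    out: list[BindingRecord] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        ba = [r for r in group if r.source == SOURCE_BA]
        if ba:
            mean_v = sum(r.value_nM for r in ba) / len(ba)
            ineqs = {r.inequality for r in ba}
            if len(ineqs) == 1:
                ineq = ineqs.pop()
            else:
                ineq = "=" if "=" in ineqs else min(ineqs)
                logger.warning(
                    "conflicting inequalities %s for %s; using %r", sorted(ineqs), key, ineq
                )
            out.append(replace(ba[0], value_nM=mean_v, inequality=ineq))
        else:
            # all qualitative (or negative) duplicates: keep the first
            out.append(group[0])
    return out


def generate_synthetic_negatives(
    positives: Sequence[BindingRecord],
    proteome: Sequence[str],
    ratio: int = 5,
    lengths: Sequence[int] = tuple(range(8, 16)),
    seed: int = 0,
) -> list[BindingRecord]:
    """Sample decoy non-binders from a proteome for each allele.

    For an allele with n positives, ``ratio * n`` negatives are drawn:
    k-mers sampled uniformly at random from the proteome, the requested
    lengths represented as equally as integer division allows (remainder
    spread over the shortest lengths), affinity uniform in
    [20000, 50000] nM with inequality ">".
    """
    if not proteome:
        raise ValueError("proteome must be nonempty")
    lengths = sorted(lengths)
    usable = {
        L: [s for s in proteome if len(s) >= L] for L in lengths
    }
    for L, seqs in usable.items():
        if not seqs:
            raise ValueError(f"no proteome sequence long enough for {L}-mers")

    counts: dict[str, int] = {}
    for r in positives:
        counts[r.allele] = counts.get(r.allele, 0) + 1

    rng = np.random.default_rng(seed)
    out: list[BindingRecord] = []
    for allele in sorted(counts):
        n_neg = ratio * counts[allele]
        base, rem = divmod(n_neg, len(lengths))
        per_length = {L: base + (1 if i < rem else 0) for i, L in enumerate(lengths)}
        for L in lengths:
            seqs = usable[L]
            for _ in range(per_length[L]):
                s = seqs[rng.integers(len(seqs))]
                start = int(rng.integers(len(s) - L + 1))
                kmer = s[start : start + L]
                value = float(rng.uniform(20_000.0, MAX_NM))
                out.append(
                    BindingRecord(
                        allele=allele,
                        peptide=kmer,
                        value_nM=value,
                        inequality=">",
                        source=SOURCE_NEG,
                    )
                )
    return out


def split_train_validation(
    records: Sequence[BindingRecord],
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[BindingRecord], list[BindingRecord]]:
    """Allele-balanced split on distinct (allele, peptide) pairs.

    Per allele, floor(fraction * n_pairs) distinct pairs go to
    validation; repeated observations of a pair always follow their pair,
    so no pair straddles the split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    by_allele: dict[str, list[str]] = {}
    for r in records:
        pairs = by_allele.setdefault(r.allele, [])
        if r.peptide not in pairs:
            pairs.append(r.peptide)

    rng = np.random.default_rng(seed)
    val_pairs: set[tuple[str, str]] = set()
    for allele in sorted(by_allele):
        peptides = sorted(by_allele[allele])
        n_val = int(fraction * len(peptides))
        if n_val:
            chosen = rng.choice(len(peptides), size=n_val, replace=False)
            val_pairs.update((allele, peptides[i]) for i in chosen)

    train, validation = [], []
    for r in records:
        (validation if (r.allele, r.peptide) in val_pairs else train).append(r)
    return train, validation


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["allele", "peptide", "value_nM", "inequality", "source"]


def read_binding_tsv(path) -> list[BindingRecord]:
    """Read binding records from delimited text (tab or comma).

    Expects a header ``allele peptide value_nM inequality source``.
    Peptides containing non-standard residues are dropped with a warning.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    out = []
    for row in df.itertuples(index=False):
        peptide = str(row.peptide)
        if set(peptide) - _AA_SET:
            logger.warning("dropping peptide %r: non-standard residues", peptide)
            continue
        out.append(
            BindingRecord(
                allele=str(row.allele),
                peptide=peptide,
                value_nM=float(row.value_nM),
                inequality=str(row.inequality),
                source=str(row.source),
            )
        )
    return out


def write_binding_tsv(records: Iterable[BindingRecord], path) -> None:
    """Write binding records as tab-delimited text with header."""
    import pandas as pd

    df = pd.DataFrame(
        [(r.allele, r.peptide, r.value_nM, r.inequality, r.source) for r in records],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_proteome_fasta(path) -> list[str]:
    """Read protein sequences from FASTA, keeping standard residues only."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if set(s) - _AA_SET:
            logger.warning("proteome sequence %s contains non-standard residues; kept as-is "
                           "but sampled k-mers may be rejected downstream", rec.id)
        out.append(s)
    return out
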