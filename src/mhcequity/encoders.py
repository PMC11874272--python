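"""Sequence representations for peptides and MHC molecules.

Peptides of length 8–15 are mapped onto a fixed 15-mer frame: the first
and last four residues anchor the ends and the remaining middle residues
are centered in the seven interior slots, with ``X`` filling unused slots.
MHC molecules are represented by a 34-residue pseudosequence — the
peptide-contacting pocket positions of the mature class I heavy chain.
Similarity between pseudosequences is the BLOSUM62 score distance

    d(A, B) = 1 - s(A, B) / sqrt(s(A, A) * s(B, B))

where s is the ungapped position-wise sum of BLOSUM62 substitution
scores, so d(A, A) = 0 and d is symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PEPTIDE_FRAME = 15
PSEUDOSEQUENCE_LENGTH = 34

#: 1-based positions on the mature class I heavy chain that form the
#: standard 34-residue binding-pocket pseudosequence.
PSEUDOSEQUENCE_POSITIONS = (
    31, 33, 48, 69, 83, 86, 87, 90, 91, 93, 94, 97, 98, 100, 101, 104,
    105, 108, 119, 121, 123, 138, 140, 142, 167, 171, 174, 176, 180,
    182, 183, 187, 191, 195,
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# Dense integer lookup over the 20-aa alphabet, index order AMINO_ACIDS.
BLOSUM62_MATRIX = np.array(
    [[int(_BLOSUM62[a][b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS],
    dtype=np.int64,
)


class PseudosequenceExclusionError(ValueError):
    """Raised when an extracted pseudosequence contains an unknown residue."""


@dataclass(frozen=True)
class Pseudosequence:
    """A 34-residue binding-pocket representation of one MHC allele."""

    allele: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != PSEUDOSEQUENCE_LENGTH:
            raise ValueError(
                f"pseudosequence for {self.allele!r} has length "
                f"{len(self.residues)}, expected {PSEUDOSEQUENCE_LENGTH}"
            )
        if PAD in self.residues:
            raise PseudosequenceExclusionError(
                f"pseudosequence for {self.allele!r} contains unknown residue 'X'"
            )
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"pseudosequence for {self.allele!r} contains non-standard "
                f"residues {sorted(bad)}"
            )


def pad_peptide(peptide: str) -> str:
    """Place a peptide of length 8–15 into the fixed 15-mer frame.

    The first four residues go to positions 1–4, the last four to
    positions 12–15, and the middle ``len - 8`` residues are centered in
    the seven interior slots (left-biased: any extra pad slot goes to the
    right). Unused slots are ``X``.
    """
    n = len(peptide)
    if not 8 <= n <= PEPTIDE_FRAME:
        raise ValueError(f"peptide length {n} outside [8, 15]: {peptide!r}")
    if n == PEPTIDE_FRAME:
        return peptide
    middle = peptide[4 : n - 4]
    slots = PEPTIDE_FRAME - 8  # 7 interior slots
    left = (slots - len(middle)) // 2
    right = slots - len(middle) - left
    return peptide[:4] + PAD * left + middle + PAD * right + peptide[n - 4 :]


def unpad_peptide(padded: str) -> str:
    """Strip pad characters, recovering the original peptide."""
    return padded.replace(PAD, "")


def encode_sequence(padded: str, scheme: str = "onehot") -> np.ndarray:
    """Encode a (padded) sequence as an L x 20 real matrix.

    ``scheme`` is ``"onehot"`` or ``"blosum62row"`` (the residue's row of
    BLOSUM62 against the 20 standard amino acids). The pad residue ``X``
    is a row of 20 zeros under both schemes.
    """
    if scheme not in ("onehot", "blosum62row"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    out = np.zeros((len(padded), 20), dtype=np.float64)
    for i, ch in enumerate(padded):
        if ch == PAD:
            continue
        j = _AA_INDEX.get(ch)
        if j is None:
            raise ValueError(f"unknown character {ch!r} at position {i}")
        if scheme == "onehot":
            out[i, j] = 1.0
        else:
            out[i] = BLOSUM62_MATRIX[j]
    return out


def extract_pseudosequence(
    full_sequence: str,
    positions: Sequence[int] = PSEUDOSEQUENCE_POSITIONS,
    allele: str = "",
) -> Pseudosequence:
    """Extract the 34-residue pseudosequence from a mature protein sequence.

    ``positions`` are 1-based indices into the mature chain. An ``X`` at
    any extracted position excludes the allele
    (:class:`PseudosequenceExclusionError`).
    """
    if len(positions) != PSEUDOSEQUENCE_LENGTH:
        raise ValueError(f"expected {PSEUDOSEQUENCE_LENGTH} positions, got {len(positions)}")
    if len(full_sequence) < max(positions):
        raise ValueError(
            f"sequence length {len(full_sequence)} shorter than max position {max(positions)}"
        )
    residues = "".join(full_sequence[p - 1] for p in positions)
    if PAD in residues:
        logger.warning("allele %r excluded: pseudosequence contains 'X'", allele)
        raise PseudosequenceExclusionError(
            f"extracted pseudosequence for {allele!r} contains unknown residue 'X'"
        )
    return Pseudosequence(allele=allele, residues=residues)


def _as_residues(p) -> str:
    return p.residues if isinstance(p, Pseudosequence) else str(p)


def _seq_to_idx(residues: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in residues), dtype=np.int64, count=len(residues))


def blosum62_score(a: str, b: str) -> int:
    """Ungapped position-wise BLOSUM62 score of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    ia, ib = _seq_to_idx(a), _seq_to_idx(b)
    return int(BLOSUM62_MATRIX[ia, ib].sum())


def blosum62_distance(p1, p2) -> float:
    """BLOSUM62 score distance between two pseudosequences.

    d = 1 - s(A,B)/sqrt(s(A,A)·s(B,B)); 0 for identical sequences,
    symmetric, and bounded by roughly [0, 2] for real sequences.
    """
    a, b = _as_residues(p1), _as_residues(p2)
    if len(a) != len(b):
        raise ValueError(f"unequal pseudosequence lengths {len(a)} vs {len(b)}")
    s_ab = blosum62_score(a, b)
    s_aa = blosum62_score(a, a)
    s_bb = blosum62_score(b, b)
    return 1.0 - s_ab / float(np.sqrt(s_aa * s_bb))


def pairwise_distance_matrix(residues: Iterable[str]) -> np.ndarray:
    """Dense symmetric matrix of BLOSUM62 distances over many sequences.

    Vectorized over positions; quadratic in the number of sequences.
    """
    seqs = [_as_residues(r) for r in residues]
    if not seqs:
        return np.zeros((0, 0))
    L = len(seqs[0])
    idx = np.stack([_seq_to_idx(s) for s in seqs])  # (n, L)
    if idx.shape[1] != L or any(len(s) != L for s in seqs):
        raise ValueError("sequences must share one length")
    n = len(seqs)
    self_scores = BLOSUM62_MATRIX[idx, idx].sum(axis=1).astype(np.float64)
    cross = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        # score of seq i against all: lookup per position then sum
        cross[i] = BLOSUM62_MATRIX[idx[i][None, :], idx].sum(axis=1)
    denom = np.sqrt(self_scores[:, None] * self_scores[None, :])
    d = 1.0 - cross / denom
    np.fill_diagonal(d, 0.0)
    return d


def distances_to_query(query: str, residues: Sequence[str]) -> np.ndarray:
    """BLOSUM62 distances from one query sequence to each of ``residues``."""
    q = _as_residues(query)
    iq = _seq_to_idx(q)
    s_qq = float(BLOSUM62_MATRIX[iq, iq].sum())
    out = np.empty(len(residues), dtype=np.float64)
    for k, r in enumerate(residues):
        ir = _seq_to_idx(_as_residues(r))
        if len(ir) != len(iq):
            raise ValueError("unequal pseudosequence lengths")
        s_rr = float(BLOSUM62_MATRIX[ir, ir].sum())
        s_qr = float(BLOSUM62_MATRIX[iq, ir].sum())
        out[k] = 1.0 - s_qr / np.sqrt(s_qq * s_rr)
    return out


def read_pseudosequences(path) -> dict[str, str]:
    """Read an allele → pseudosequence map from 2-column TSV or FASTA."""
    from pathlib import Path

    text = Path(path).read_text()
    result: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        from io import StringIO
        from Bio import SeqIO

        for rec in SeqIO.parse(StringIO(text), "fasta"):
            result[rec.id] = str(rec.seq)
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("allele",):
                continue
            result[fields[0]] = fields[1]
    return result


def write_pseudosequences(pseudosequences: Mapping[str, str], path, fmt: str = "tsv") -> None:
    """Write an allele → pseudosequence map as TSV or FASTA."""
    from pathlib import Path

    lines = []
    if fmt == "tsv":
        lines.append("allele\tpseudosequence")
        for allele in sorted(pseudosequences):
            lines.append(f"{allele}\t{pseudosequences[allele]}")
    elif fmt == "fasta":
        for allele in sorted(pseudosequences):
            lines.append(f">{allele}")
            lines.append(pseudosequences[allele])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")
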