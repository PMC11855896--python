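"""Redundancy reduction ("culling") of protein sets.

Near-duplicate sequences bias any group-level statistic toward whatever the
duplicated family looks like, so each class is purged of sequences whose
pairwise identity exceeds a threshold (80% by default).  Identity comes from
a global alignment (BLOSUM62, gap open 10, gap extend 0.5) and is defined as
100 * matches / alignment length, gap columns included; the denominator is
switchable to the shorter sequence length.

Culling is greedy and deterministic: repeatedly find the highest-identity
pair above threshold and drop its shorter member (on equal lengths, the
lexicographically larger id), until no retained pair exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
    denominator: str = "alignment",
) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    ``denominator`` is ``"alignment"`` (alignment length, gap columns
    included) or ``"shorter"`` (length of the shorter sequence).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    matches = counts.identities
    if denominator == "alignment":
        denom = alignment.length
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom


@dataclass(frozen=True)
class CullResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]
    identity: "IdentityMatrix"


class IdentityMatrix:
    """Symmetric percent-identity matrix over a set of sequence ids."""

    def __init__(self, ids: list[str], values: np.ndarray):
        if values.shape != (len(ids), len(ids)):
            raise ValueError("shape mismatch")
        self.ids = list(ids)
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        aligner: Align.PairwiseAligner | None = None,
        denominator: str = "alignment",
    ) -> "IdentityMatrix":
        if aligner is None:
            aligner = make_aligner()
        ids = list(sequences)
        n = len(ids)
        values = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                ident = pairwise_identity(
                    sequences[ids[i]], sequences[ids[j]], aligner, denominator
                )
                values[i, j] = values[j, i] = ident
        return cls(ids, values)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def cull(
    sequences: dict[str, str],
    threshold: float = 80.0,
    aligner: Align.PairwiseAligner | None = None,
    denominator: str = "alignment",
    identity: IdentityMatrix | None = None,
) -> CullResult:
    """Greedy removal of redundant sequences.

    While some retained pair exceeds ``threshold`` percent identity, the
    highest such pair is resolved by dropping the shorter member; equal
    lengths drop the lexicographically larger id.  The retained set
    therefore keeps the longer representative of every redundant family and
    is invariant to input order.
    """
    if not sequences:
        raise ValueError("no sequences to cull")
    if identity is None:
        identity = IdentityMatrix.from_sequences(sequences, aligner, denominator)
    ids = identity.ids
    active = set(ids)
    removed: list[str] = []
    while True:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(ids):
            if a not in active:
                continue
            for b in ids[i + 1 :]:
                if b not in active:
                    continue
                ident = identity[a, b]
                if ident <= threshold:
                    continue
                if best is None or ident > best[0]:
                    best = (ident, a, b)
        if best is None:
            break
        _, a, b = best
        la, lb = len(sequences[a]), len(sequences[b])
        if la < lb or (la == lb and a > b):
            victim = a
        else:
            victim = b
        active.discard(victim)
        removed.append(victim)
    retained = tuple(sid for sid in ids if sid in active)
    return CullResult(retained=retained, removed=tuple(removed), identity=identity)
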