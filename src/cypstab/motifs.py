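"""P450 signature-motif scanning and per-column conservation.

Cytochrome P450s carry five signature motifs arranged N- to C-terminal:
helix C (WxxR), helix I (GxE/DTT/S), helix K (ExLR), PERF (PxxFxPE/DRE) and
the haem-binding motif (PFxxGxRxCxG/A) whose cysteine ligates the haem iron.
'x' accepts any residue; a set like E/D accepts either listed residue.

The scanner reports every (possibly overlapping) pattern occurrence; a
separate policy step anchors at most one window per sequence, respecting
the expected N-to-C ordering of the five motifs.  Windows are profiled into
a position frequency matrix (PFM) with per-column consensus and information
content in bits (max log2 20 ~= 4.32 for a fully conserved column).

The haem window is 15 columns: the 11-position pattern span plus 4 trailing
profiled-but-unconstrained columns, matching the motif's full printed
consensus in labile mosquito CYPs, PFSAGPRNCIGQRFA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import STANDARD_RESIDUES

ANY = frozenset(STANDARD_RESIDUES)

HAEM_CONSENSUS_LABILE = "PFSAGPRNCIGQRFA"


def _pos(spec: str) -> frozenset[str]:
    return ANY if spec == "x" else frozenset(spec)


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered pattern of fixed residues, wildcards and alternative sets.

    ``window`` may exceed the pattern span: trailing columns are included in
    the extracted window (and the PFM) but not pattern-constrained.
    """

    name: str
    positions: tuple[frozenset[str], ...]
    window: int = 0

    def __post_init__(self):
        if self.window < len(self.positions):
            object.__setattr__(self, "window", len(self.positions))

    @property
    def span(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start0: int) -> bool:
        if start0 + self.window > len(sequence):
            return False
        return all(
            sequence[start0 + i] in allowed
            for i, allowed in enumerate(self.positions)
        )


def _motif(name: str, pattern: str, window: int = 0) -> MotifDefinition:
    return MotifDefinition(
        name, tuple(_pos(p) for p in pattern.split(",")), window
    )


# N->C order: helix C < helix I < helix K < PERF < haem
BUILTIN_MOTIFS: dict[str, MotifDefinition] = {
    m.name: m
    for m in (
        _motif("helixC", "W,x,x,R"),
        _motif("helixI", "G,x,ED,T,TS"),
        _motif("helixK", "E,x,L,R"),
        _motif("PERF", "P,x,x,F,x,P,ED,R,E"),
        _motif("haem", "P,F,x,x,G,x,R,x,C,x,GA", window=15),
    )
}

MOTIF_ORDER = ("helixC", "helixI", "helixK", "PERF", "haem")


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    motif: str
    start: int  # 1-based
    window: str

    def __post_init__(self):
        definition = BUILTIN_MOTIFS.get(self.motif)
        if definition is not None and not definition.matches_at(
            self.window, 0
        ):
            raise ValueError(
                f"window {self.window!r} does not satisfy motif {self.motif}"
            )


def scan(
    sequence: str, motif: MotifDefinition, sequence_id: str = ""
) -> list[MotifMatch]:
    """All (possibly overlapping) occurrences of a motif, N->C order."""
    seq = sequence.upper()
    out = []
    for start0 in range(len(seq) - motif.window + 1):
        if motif.matches_at(seq, start0):
            out.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    motif=motif.name,
                    start=start0 + 1,
                    window=seq[start0 : start0 + motif.window],
                )
            )
    return out


def best_window_per_sequence(
    matches: list[MotifMatch], previous_anchor_end: int = 0
) -> MotifMatch | None:
    """Select at most one window: the first match starting after the most
    recent upstream anchor (motifs are ordered helixC < helixI < helixK <
    PERF < haem along the chain)."""
    for match in sorted(matches, key=lambda m: m.start):
        if match.start > previous_anchor_end:
            return match
    return None


def anchor_motifs(
    sequence: str,
    sequence_id: str = "",
    motifs: dict[str, MotifDefinition] = BUILTIN_MOTIFS,
    order: tuple[str, ...] = MOTIF_ORDER,
) -> dict[str, MotifMatch]:
    """One anchored window per motif per sequence, enforcing N->C order.

    Each motif's window must begin strictly after the previous anchored
    motif's window ends; motifs with no admissible match are absent from
    the result."""
    anchored: dict[str, MotifMatch] = {}
    previous_end = 0
    for name in order:
        if name not in motifs:
            continue
        match = best_window_per_sequence(
            scan(sequence, motifs[name], sequence_id), previous_end
        )
        if match is not None:
            anchored[name] = match
            previous_end = match.start + len(match.window) - 1
    return anchored


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    motif: str
    n_windows: int
    frequencies: pd.DataFrame = field(repr=False)  # columns x residues, percent

    @property
    def n_columns(self) -> int:
        return len(self.frequencies)

    def consensus(self) -> str:
        # argmax per column; ties break alphabetically (column order is sorted)
        return "".join(self.frequencies.idxmax(axis=1))

    def max_frequency(self) -> pd.Series:
        return self.frequencies.max(axis=1)

    def information_content(self) -> pd.Series:
        """Per-column IC in bits: log2(20) + sum p log2 p over nonzero p."""
        p = self.frequencies.to_numpy() / 100.0
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        ic = math.log2(20) + plogp.sum(axis=1)
        return pd.Series(ic, index=self.frequencies.index, name="ic_bits")


def build_pfm(windows: list[str], motif: str = "") -> PositionFrequencyMatrix:
    """Position frequency matrix from equal-length aligned windows."""
    if not windows:
        raise ValueError("no windows")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"unequal window lengths: {sorted(lengths)}")
    width = lengths.pop()
    residues = sorted(set(STANDARD_RESIDUES) | {c for w in windows for c in w})
    counts = np.zeros((width, len(residues)))
    col_of = {aa: i for i, aa in enumerate(residues)}
    for w in windows:
        for i, aa in enumerate(w):
            counts[i, col_of[aa]] += 1
    freqs = pd.DataFrame(
        100.0 * counts / len(windows),
        index=pd.RangeIndex(1, width + 1, name="column"),
        columns=residues,
    )
    return PositionFrequencyMatrix(
        motif=motif, n_windows=len(windows), frequencies=freqs
    )


def invariant_columns(
    pfm: PositionFrequencyMatrix, level: float = 100.0
) -> set[int]:
    """Columns (1-based) whose most frequent residue reaches ``level`` percent."""
    maxima = pfm.max_frequency()
    return set(maxima.index[maxima >= level - 1e-9])


def conservation_summary(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    """Per-column consensus residue, max frequency and IC, logo-ready."""
    return pd.DataFrame(
        {
            "consensus": list(pfm.consensus()),
            "max_percent": pfm.max_frequency(),
            "ic_bits": pfm.information_content(),
        }
    )
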