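"""Pepstats-style physicochemical profiling of protein sequences.

For each protein the module computes length, average molecular weight, the
formal-charge sum, the isoelectric point, per-residue composition (percent),
the nine overlapping category frequencies, and a composition-weighted
Kyte–Doolittle hydrophobicity score

    H = sum_aa f_aa(percent) * h_aa

where ``f_aa`` is the residue frequency in PERCENT and ``h_aa`` the
Kyte–Doolittle index.  With the percent convention H equals 100x the
classical mean-hydropathy (GRAVY) value; a membrane-anchored P450 with
GRAVY ~= -0.18 scores H ~= -18.

Ambiguity codes B and Z count toward composition and category frequencies
but are excluded (numerator and denominator) from hydrophobicity and the
isoelectric point, which have no published per-residue constants for them.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .scales import (
    AMBIGUOUS_RESIDUES,
    CATEGORY_NAMES,
    DEFAULT_SCALES,
    STANDARD_RESIDUES,
    VALID_RESIDUES,
    AminoAcidScales,
)


class SequenceError(ValueError):
    """Raised for empty sequences or letters outside the amino-acid alphabet."""


def _validate(sequence: str) -> str:
    if not sequence:
        raise SequenceError("empty sequence")
    seq = sequence.upper()
    for pos, letter in enumerate(seq, start=1):
        if letter not in VALID_RESIDUES:
            raise SequenceError(f"illegal residue {letter!r} at position {pos}")
    return seq


def residue_composition(sequence: str) -> dict[str, float]:
    """Residue frequencies in percent of sequence length.

    Returns a dict keyed by every observed letter (including B/Z/X);
    frequencies over observed residues sum to 100.
    """
    seq = _validate(sequence)
    n = len(seq)
    counts = Counter(seq)
    return {aa: 100.0 * c / n for aa, c in counts.items()}


def category_frequencies(
    sequence: str, scales: AminoAcidScales = DEFAULT_SCALES
) -> dict[str, float]:
    """The nine overlapping category percentages.

    Each category percentage is the summed frequency of its member residues;
    categories overlap by construction, so they are not normalised against
    each other.  On B/Z-free input Polar + Non-polar = 100 because the two
    sets partition the 20 standard residues.
    """
    comp = residue_composition(sequence)
    return {
        name: sum(comp.get(aa, 0.0) for aa in scales.categories[name])
        for name in CATEGORY_NAMES
    }


def kd_hydrophobicity(
    sequence: str, scales: AminoAcidScales = DEFAULT_SCALES
) -> float:
    """Composition-weighted Kyte–Doolittle score, H = sum f_aa(%) * h_aa.

    B/Z/X are dropped from both numerator and denominator (with a warning);
    a sequence with no standard residues is rejected.
    """
    seq = _validate(sequence)
    kept = [aa for aa in seq if aa in scales.kd_hydropathy]
    if not kept:
        raise SequenceError("no standard residues for hydrophobicity")
    if len(kept) < len(seq):
        warnings.warn(
            "ambiguous residues excluded from hydrophobicity", stacklevel=2
        )
    n = len(kept)
    counts = Counter(kept)
    return sum(100.0 * c / n * scales.kd_hydropathy[aa] for aa, c in counts.items())


def molecular_weight(
    sequence: str, scales: AminoAcidScales = DEFAULT_SCALES
) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water.

    B and Z use the mass averaged over their residue pair; X has no defined
    mass and is excluded with a warning.
    """
    seq = _validate(sequence)
    masses = scales.average_residue_mass
    unknown = [aa for aa in seq if aa not in masses]
    if unknown:
        warnings.warn("residues without mass excluded from MW", stacklevel=2)
    return sum(masses[aa] for aa in seq if aa in masses) + scales.water_mass


def net_charge(sequence: str, scales: AminoAcidScales = DEFAULT_SCALES) -> float:
    """Formal-charge sum over the sequence (D,E −1; K,R +1; H +0.5; B,Z −0.5)."""
    seq = _validate(sequence)
    return sum(scales.charge_of(aa) for aa in seq)


def _hh_charge(
    counts: dict[str, int], ph: float, scales: AminoAcidScales
) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Basic groups (N-terminus, H, K, R) contribute +1/(1+10^(pH−pKa));
    acidic groups (C-terminus, C, D, E, Y) contribute −1/(1+10^(pKa−pH)).
    """
    charge = 1.0 / (1.0 + 10.0 ** (ph - scales.pka["N_TERMINUS"]))
    charge -= 1.0 / (1.0 + 10.0 ** (scales.pka["C_TERMINUS"] - ph))
    for aa in scales.basic_side_chains:
        n = counts.get(aa, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - scales.pka[aa]))
    for aa in scales.acidic_side_chains:
        n = counts.get(aa, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (scales.pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    scales: AminoAcidScales = DEFAULT_SCALES,
    tol: float = 1e-4,
    include_termini: bool = True,
) -> float | None:
    """pH at which the Henderson–Hasselbalch net charge crosses zero.

    Solved by bisection on [0, 14] to |charge| < ``tol``.  B/Z/X carry no
    pKa and are ignored.  Returns None when nothing ionizes (only possible
    with ``include_termini=False``).
    """
    seq = _validate(sequence)
    counts = Counter(aa for aa in seq if aa in scales.pka)
    if not include_termini and not counts:
        return None
    lo, hi = 0.0, 14.0
    mid = 7.0
    # bisect until the bracket is far below the charge tolerance: the net
    # charge is monotone decreasing in pH, so this nails the zero crossing
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        q = _hh_charge(counts, mid, scales)
        if abs(q) < tol and hi - lo < 1e-9:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


@dataclass(frozen=True)
class ProteinFeatureVector:
    """Per-protein physicochemical summary (one row of the feature table)."""

    sequence_id: str
    length: int
    molecular_weight: float
    charge: float
    isoelectric_point: float | None
    hydrophobicity: float
    composition: dict[str, float]
    category_percent: dict[str, float]

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "length": self.length,
            "molecular_weight": self.molecular_weight,
            "charge": self.charge,
            "isoelectric_point": self.isoelectric_point,
            "hydrophobicity": self.hydrophobicity,
        }
        for name in CATEGORY_NAMES:
            row[name] = self.category_percent[name]
        for aa in STANDARD_RESIDUES:
            row[f"f_{aa}"] = self.composition.get(aa, 0.0)
        for aa in AMBIGUOUS_RESIDUES:
            if aa in self.composition:
                row[f"f_{aa}"] = self.composition[aa]
        return row


def profile_sequence(
    sequence_id: str, sequence: str, scales: AminoAcidScales = DEFAULT_SCALES
) -> ProteinFeatureVector:
    seq = _validate(sequence)
    return ProteinFeatureVector(
        sequence_id=sequence_id,
        length=len(seq),
        molecular_weight=molecular_weight(seq, scales),
        charge=net_charge(seq, scales),
        isoelectric_point=isoelectric_point(seq, scales),
        hydrophobicity=kd_hydrophobicity(seq, scales),
        composition=residue_composition(seq),
        category_percent=category_frequencies(seq, scales),
    )


def profile_fasta(
    path, scales: AminoAcidScales = DEFAULT_SCALES
) -> pd.DataFrame:
    """Profile every record of a protein FASTA into a feature DataFrame.

    The index is the FASTA record id; columns are the ProteinFeatureVector
    fields with per-residue frequencies as ``f_<aa>``.
    """
    rows = {}
    for record in SeqIO.parse(str(path), "fasta"):
        vec = profile_sequence(record.id, str(record.seq), scales)
        rows[record.id] = vec.as_row()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sequence_id"
    # absent residues are structural zeros, not missing data
    freq_cols = [c for c in frame.columns if c.startswith("f_")]
    frame[freq_cols] = frame[freq_cols].fillna(0.0)
    return frame
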