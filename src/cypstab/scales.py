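"""Residue-level constants used throughout the package.

The tables are shipped as a versioned JSON data file and exposed through a
single :class:`AminoAcidScales` instance.  They follow the EMBOSS/Pepstats
conventions: average (not monoisotopic) residue masses, the EMBOSS pKa set
for ionizable groups, the Kyte–Doolittle hydropathy index, and the nine
overlapping residue categories (Tiny, Small, Aliphatic, Aromatic, Non-polar,
Polar, Charged, Basic, Acidic) used for composition summaries.

The ambiguity codes B (Asn/Asp) and Z (Gln/Glu) carry averaged masses and a
−0.5 charge, and belong to the category sets that list them; they have no
hydropathy or pKa entry and are excluded from those computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "BZX"
VALID_RESIDUES = frozenset(STANDARD_RESIDUES + AMBIGUOUS_RESIDUES)

CATEGORY_NAMES = (
    "Tiny",
    "Small",
    "Aliphatic",
    "Aromatic",
    "Non-polar",
    "Polar",
    "Charged",
    "Basic",
    "Acidic",
)


@dataclass(frozen=True)
class AminoAcidScales:
    """Bundle of residue-level constants.

    Attributes
    ----------
    kd_hydropathy
        Kyte–Doolittle hydropathy index per standard residue
        (Ile +4.5 … Arg −4.5).
    average_residue_mass
        Average residue masses in Da (water already subtracted); peptide
        mass is the sum of residue masses plus one water.
    water_mass
        Mass of one water molecule in Da.
    pka
        pKa of ionizable side chains and the free termini
        (keys ``N_TERMINUS`` / ``C_TERMINUS``).
    residue_charge
        Integer/half-integer formal charge table used by the Pepstats-style
        ``Charge`` statistic.
    categories
        The nine overlapping residue category sets.
    """

    version: str
    kd_hydropathy: dict[str, float]
    average_residue_mass: dict[str, float]
    water_mass: float
    pka: dict[str, float]
    acidic_side_chains: tuple[str, ...]
    basic_side_chains: tuple[str, ...]
    residue_charge: dict[str, float]
    categories: dict[str, frozenset[str]] = field(repr=False)

    @classmethod
    def from_json(cls, text: str) -> "AminoAcidScales":
        raw = json.loads(text)
        return cls(
            version=raw["version"],
            kd_hydropathy=raw["kd_hydropathy"],
            average_residue_mass=raw["average_residue_mass"],
            water_mass=raw["water_mass"],
            pka=raw["pka"],
            acidic_side_chains=tuple(raw["acidic_side_chains"]),
            basic_side_chains=tuple(raw["basic_side_chains"]),
            residue_charge=raw["residue_charge"],
            categories={k: frozenset(v) for k, v in raw["categories"].items()},
        )

    def charge_of(self, residue: str) -> float:
        return self.residue_charge.get(residue, 0.0)

    def as_json(self, indent: int = 2) -> str:
        out = {
            "version": self.version,
            "kd_hydropathy": self.kd_hydropathy,
            "average_residue_mass": self.average_residue_mass,
            "water_mass": self.water_mass,
            "pka": self.pka,
            "acidic_side_chains": list(self.acidic_side_chains),
            "basic_side_chains": list(self.basic_side_chains),
            "residue_charge": self.residue_charge,
            "categories": {k: sorted(v) for k, v in self.categories.items()},
        }
        return json.dumps(out, indent=indent)


def load_default_scales() -> AminoAcidScales:
    """Load the packaged scale tables."""
    text = resources.files("cypstab.data").joinpath("scales.json").read_text()
    return AminoAcidScales.from_json(text)


DEFAULT_SCALES = load_default_scales()
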