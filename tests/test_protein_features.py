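"""Physicochemical profiling: compositions, categories, hydrophobicity,
molecular weight, charge and isoelectric point."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cypstab.protein_features import (
    SequenceError,
    category_frequencies,
    isoelectric_point,
    kd_hydrophobicity,
    molecular_weight,
    net_charge,
    profile_sequence,
    residue_composition,
)
from cypstab.scales import DEFAULT_SCALES, STANDARD_RESIDUES

standard_seq = st.text(alphabet=STANDARD_RESIDUES, min_size=1, max_size=200)


class TestResidueComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 100.0}),
            ("ACDE", {"A": 25.0, "C": 25.0, "D": 25.0, "E": 25.0}),
        ],
    )
    def test_simple_compositions(self, seq, expected):
        assert residue_composition(seq) == expected

    def test_rejects_empty_and_illegal(self):
        with pytest.raises(SequenceError):
            residue_composition("")
        with pytest.raises(SequenceError, match="position 3"):
            residue_composition("AC1DE")

    @given(standard_seq)
    def test_frequencies_sum_to_100(self, seq):
        assert math.isclose(sum(residue_composition(seq).values()), 100.0,
                            abs_tol=1e-9)


class TestCategories:
    def test_aliphatic_only(self):
        cats = category_frequencies("ILV")
        assert cats["Aliphatic"] == 100.0
        assert cats["Aromatic"] == 0.0

    def test_overlapping_sets(self):
        cats = category_frequencies("DEHK")
        assert cats["Polar"] == 100.0
        assert cats["Charged"] == 100.0
        assert cats["Acidic"] == 50.0
        assert cats["Basic"] == 50.0

    @given(standard_seq)
    def test_polar_nonpolar_complementarity(self, seq):
        # Polar and Non-polar partition the 20 standard residues
        cats = category_frequencies(seq)
        assert math.isclose(cats["Polar"] + cats["Non-polar"], 100.0,
                            abs_tol=1e-9)

    def test_bz_count_in_categories(self):
        cats = category_frequencies("BZ")
        assert cats["Charged"] == 100.0
        assert cats["Acidic"] == 100.0
        assert cats["Small"] == 50.0  # B only


class TestHydrophobicity:
    def test_single_residue_extremes(self):
        assert kd_hydrophobicity("IIII") == pytest.approx(450.0)
        assert kd_hydrophobicity("RRRR") == pytest.approx(-450.0)

    def test_uniform_composition_matches_index_sum(self):
        # 5% of each residue -> H = 5 * sum of the 20 index values
        seq = "".join(STANDARD_RESIDUES)
        expected = 5.0 * sum(DEFAULT_SCALES.kd_hydropathy.values())
        assert kd_hydrophobicity(seq) == pytest.approx(expected)

    @given(standard_seq)
    def test_permutation_invariance(self, seq):
        shuffled = "".join(sorted(seq))
        assert kd_hydrophobicity(seq) == pytest.approx(
            kd_hydrophobicity(shuffled)
        )

    @given(st.text(alphabet=STANDARD_RESIDUES, min_size=5, max_size=120))
    def test_h_is_100x_gravy(self, seq):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        gravy = ProteinAnalysis(seq).gravy()
        assert kd_hydrophobicity(seq) / 100.0 == pytest.approx(gravy, abs=1e-9)

    def test_ambiguous_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            h = kd_hydrophobicity("IIB")
        assert h == pytest.approx(450.0)  # B dropped from both sides
        with pytest.raises(SequenceError):
            kd_hydrophobicity("BZX")


class TestMolecularWeight:
    @pytest.mark.parametrize("seq", ["G", "GG", "ACDEFGHIKLMNPQRSTVWY"])
    def test_against_biopython_average_masses(self, seq):
        from Bio.SeqUtils import molecular_weight as bio_mw

        ours = molecular_weight(seq)
        theirs = bio_mw(seq, seq_type="protein")
        assert ours == pytest.approx(theirs, rel=1e-4)

    @given(standard_seq, standard_seq)
    def test_concatenation_additivity(self, s1, s2):
        water = DEFAULT_SCALES.water_mass
        assert molecular_weight(s1 + s2) == pytest.approx(
            molecular_weight(s1) + molecular_weight(s2) - water
        )


class TestCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [("KRDE", 0.0), ("KKH", 2.5), ("AGSTNQ", 0.0), ("BZ", -1.0)],
    )
    def test_charge_table_sums(self, seq, expected):
        assert net_charge(seq) == expected


class TestIsoelectricPoint:
    def test_termini_only_closed_form(self):
        # one N-terminal base + one C-terminal acid -> midpoint of the pKa's
        pka = DEFAULT_SCALES.pka
        expected = 0.5 * (pka["N_TERMINUS"] + pka["C_TERMINUS"])
        assert isoelectric_point("AAAA") == pytest.approx(expected, abs=1e-3)

    def test_adding_lysines_never_lowers_pi(self):
        values = [isoelectric_point("AAAA" + "K" * k) for k in range(5)]
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))

    def test_bisection_matches_grid_scan(self, rng):
        from cypstab.protein_features import _hh_charge
        from collections import Counter

        grid = np.arange(0.0, 14.0, 0.001)
        residues = np.array(list(STANDARD_RESIDUES))
        for _ in range(100):
            n = int(rng.integers(5, 80))
            seq = "".join(rng.choice(residues, size=n))
            counts = Counter(aa for aa in seq if aa in DEFAULT_SCALES.pka)
            charges = np.array(
                [_hh_charge(counts, ph, DEFAULT_SCALES) for ph in grid]
            )
            grid_pi = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq) == pytest.approx(grid_pi, abs=0.01)


def test_profile_sequence_is_consistent():
    vec = profile_sequence("p1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    row = vec.as_row()
    assert row["length"] == 33
    assert row["Polar"] + row["Non-polar"] == pytest.approx(100.0)
    assert row["hydrophobicity"] == pytest.approx(
        kd_hydrophobicity("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    )
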