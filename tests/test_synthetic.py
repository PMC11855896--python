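"""The synthetic cohort generator: determinism, planted structure, errors."""

import filecmp

import numpy as np
import pytest

from cypstab.motifs import BUILTIN_MOTIFS, HAEM_CONSENSUS_LABILE, scan
from cypstab.protein_features import residue_composition
from cypstab.synthetic import (
    CohortConfig,
    ConfigurationError,
    GenerationError,
    LABILE_COMPOSITION,
    STABLE_COMPOSITION,
    generate_cohort,
    null_config,
    sample_gene_model,
    sample_protein,
)


class TestConfig:
    def test_composition_must_sum_to_100(self):
        bad = dict(STABLE_COMPOSITION)
        bad["A"] += 5.0
        with pytest.raises(ConfigurationError, match="sums to"):
            CohortConfig(stable_composition=bad).validate()

    def test_defaults_are_valid(self):
        CohortConfig().validate()

    def test_too_few_labile_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="labile"):
            CohortConfig(genes_per_class=(5, 3)).validate()


class TestSampleProtein:
    def test_pure_alanine(self, rng):
        assert sample_protein({"A": 100.0}, 50, [], rng) == "A" * 50

    def test_planted_haem_is_the_only_match(self, rng):
        comp = dict(STABLE_COMPOSITION)
        seq = sample_protein(
            comp, 200, [(BUILTIN_MOTIFS["haem"], "fixed_consensus")], rng
        )
        matches = scan(seq, BUILTIN_MOTIFS["haem"])
        assert [m.window for m in matches] == [HAEM_CONSENSUS_LABILE]

    def test_too_short_for_motifs(self, rng):
        with pytest.raises(GenerationError):
            sample_protein(
                {"A": 100.0}, 10, [(BUILTIN_MOTIFS["haem"], "fixed_consensus")],
                rng,
            )

    def test_leucine_contrast_between_class_setpoints(self, rng):
        """Mean Leu% tracks the class set-points (stable > labile)."""
        means = {}
        for name, comp in (
            ("stable", STABLE_COMPOSITION),
            ("labile", LABILE_COMPOSITION),
        ):
            vals = [
                residue_composition(
                    sample_protein(comp, 510, [], rng, composition_cv=0.04)
                )["L"]
                for _ in range(50)
            ]
            means[name] = np.mean(vals)
            # quota sampling keeps the cohort mean near the set-point
            assert means[name] == pytest.approx(comp["L"], abs=0.2)
        assert means["stable"] > means["labile"]


class TestSampleGeneModel:
    def test_single_exon(self, rng):
        spans, seq = sample_gene_model(1, [900], [], 0.5, rng)
        assert spans == [(1, 900)]
        assert len(seq) == 900

    def test_additivity(self, rng):
        spans, seq = sample_gene_model(2, [300, 200], [500], 0.5, rng)
        assert spans == [(1, 300), (801, 1000)]
        assert len(seq) == 1000

    def test_gc_matches_target_on_long_sequence(self, rng):
        _, seq = sample_gene_model(1, [10_000], [], 0.45, rng)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.45, abs=0.02)

    @pytest.mark.parametrize(
        "args", [(0, [], []), (2, [300, -5], [100]), (2, [300, 200], [])]
    )
    def test_invalid_parts_rejected(self, rng, args):
        with pytest.raises(GenerationError):
            sample_gene_model(*args, 0.5, rng)


class TestGenerateCohort:
    def test_count_conservation(self):
        cohort = generate_cohort(CohortConfig(seed=2, genes_per_class=(10, 10)))
        assert len(cohort.genes) == 20
        assert len(cohort.truth_frame) == 20
        assert cohort.truth_frame["class"].value_counts().to_dict() == {
            "stable": 10,
            "labile": 10,
        }
        assert not cohort.truth_frame.index.duplicated().any()

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = CohortConfig(seed=11, genes_per_class=(6, 6), n_species=2)
        paths_a = generate_cohort(config).write(tmp_path / "a")
        paths_b = generate_cohort(config).write(tmp_path / "b")
        for name in paths_a:
            assert filecmp.cmp(paths_a[name], paths_b[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a = generate_cohort(CohortConfig(seed=1, genes_per_class=(6, 6)))
        b = generate_cohort(CohortConfig(seed=2, genes_per_class=(6, 6)))
        assert a.proteins() != b.proteins()

    def test_every_labile_protein_carries_the_haem_consensus(self, small_cohort):
        for gene in small_cohort.genes:
            if gene.label == "labile":
                assert HAEM_CONSENSUS_LABILE in gene.protein

    def test_gene_length_additivity_for_all_genes(self, small_cohort):
        for gene in small_cohort.genes:
            exon_total = sum(e - s + 1 for s, e in gene.exon_spans)
            intron_total = len(gene.genome_sequence) - exon_total
            assert intron_total >= 0

    def test_ortholog_table_is_a_partition(self, default_cohort):
        frame = default_cohort.ortholog_frame
        assert not frame["gene_id"].duplicated().any()
        assert set(frame["gene_id"]) == set(default_cohort.truth_frame.index)

    def test_null_config_removes_all_contrasts(self):
        cfg = null_config(seed=5)
        assert cfg.stable_composition == cfg.labile_composition
        assert cfg.genomic["stable"] == cfg.genomic["labile"]
        cohort = generate_cohort(cfg)
        for gene in cohort.genes:
            assert HAEM_CONSENSUS_LABILE in gene.protein

    def test_annotation_counts_match_proportions(self, default_cohort):
        cfg = default_cohort.config
        ann = default_cohort.annotation_frame
        truth = default_cohort.truth_frame
        stable = set(truth.index[truth["class"] == "stable"])
        for term, (f_stable, _) in cfg.term_proportions.items():
            genes = set(ann.loc[ann["term_id"] == term, "gene_id"])
            expected = int(round(f_stable * len(stable)))
            assert len(genes & stable) == expected
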