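"""Readers, writers and identifier normalization round trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import bundle_from_array
from mirreg.core_io import (
    ExpressionBundle,
    PromoterRecord,
    TargetMap,
    detection_from_pvalues,
    normalize_gene_id,
    normalize_mirna_id,
    read_annotation,
    read_expression_bundle,
    read_fasta_promoters,
    read_target_pairs,
    write_annotation,
    write_expression_bundle,
    write_fasta_promoters,
    write_target_pairs,
)
from mirreg.synthetic_data import SimConfig, generate_bundle, write_sim_outputs


class TestExpressionBundle:
    def test_round_trip_small_fixture(self, tmp_path):
        bundle = bundle_from_array(np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]]))
        paths = [tmp_path / n for n in ("v.tsv", "d.tsv", "s.tsv")]
        write_expression_bundle(bundle, *paths)
        back = read_expression_bundle(*paths)
        assert back.feature_ids == bundle.feature_ids
        assert back.design == bundle.design
        assert np.allclose(back.values.to_numpy(), bundle.values.to_numpy())
        assert len(back.patients) == 2

    def test_round_trip_generator_output(self, tmp_path, sim_default):
        paths = [tmp_path / n for n in ("v.tsv", "d.tsv", "s.tsv")]
        write_expression_bundle(sim_default.mrna, *paths)
        back = read_expression_bundle(*paths, feature_kind="gene")
        assert back.feature_ids == sim_default.mrna.feature_ids
        assert np.allclose(back.values.to_numpy(), sim_default.mrna.values.to_numpy())
        assert back.detection.equals(sim_default.mrna.detection)

    def test_unpaired_design_rejected(self):
        values = pd.DataFrame(
            np.ones((2, 4)), index=["A", "B"], columns=["s1", "s2", "s3", "s4"]
        )
        with pytest.raises(ValueError, match="unpaired design"):
            ExpressionBundle(
                values=values,
                detection=values.astype(bool),
                design=[("P1", "tumor"), ("P1", "tumor"), ("P2", "tumor"), ("P2", "normal")],
            )

    def test_missing_tissue_rejected(self):
        values = pd.DataFrame(np.ones((1, 2)), index=["A"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="unpaired design"):
            ExpressionBundle(
                values=values,
                detection=values.astype(bool),
                design=[("P1", "tumor"), ("P2", "tumor")],
            )

    def test_dimension_mismatch_rejected(self):
        values = pd.DataFrame(np.ones((2, 2)), index=["A", "B"], columns=["s1", "s2"])
        detection = pd.DataFrame(np.ones((1, 2), dtype=bool), index=["A"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="dimension mismatch"):
            ExpressionBundle(values=values, detection=detection, design=[("P1", "tumor"), ("P1", "normal")])

    def test_duplicate_feature_ids_rejected(self):
        values = pd.DataFrame(np.ones((2, 2)), index=["A", "A"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate feature ids"):
            ExpressionBundle(
                values=values,
                detection=values.astype(bool),
                design=[("P1", "tumor"), ("P1", "normal")],
            )


class TestTargetPairs:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("hsa-miR-96\tFOXO1\nhsa-mir-96\tfoxo1\nhsa-miR-96\tFOXO3\n")
        tmap = read_target_pairs(p, "ts")
        assert len(tmap) == 2
        assert tmap.pairs == {("hsa-mir-96", "FOXO1"), ("hsa-mir-96", "FOXO3")}

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "pairs.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            tmap = read_target_pairs(p, "ts")
        assert len(tmap) == 0
        assert "empty" in caplog.text

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("m1\tg1\nm2\tg2\textra\n")
        with pytest.raises(ValueError, match="line 2"):
            read_target_pairs(p, "ts")

    def test_round_trip_generator_scale(self, tmp_path):
        rng = np.random.default_rng(0)
        pairs = {
            (f"hsa-mir-{i}", f"G{j}")
            for i, j in zip(rng.integers(0, 60, 1000), rng.integers(0, 500, 1000))
        }
        tmap = TargetMap.from_pairs("sim", pairs)
        p = tmp_path / "pairs.tsv"
        write_target_pairs(tmap, p)
        assert read_target_pairs(p, "sim").pairs == tmap.pairs


class TestFastaPromoters:
    def test_read_and_uppercase(self, tmp_path):
        p = tmp_path / "prom.fa"
        p.write_text(">geneA\nacgtACGT\n>geneB\nTTTT\n")
        records = read_fasta_promoters(p)
        assert [r.gene_id for r in records] == ["GENEA", "GENEB"]
        assert records[0].sequence == "ACGTACGT"
        assert all(r.cpg_class == "unclassified" for r in records)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "prom.fa"
        p.write_text(">g1\nACGT\n>G1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta_promoters(p)

    def test_round_trip(self, tmp_path):
        records = [PromoterRecord("G1", "ACGTACGT"), PromoterRecord("G2", "CGCGNACG")]
        p = tmp_path / "prom.fa"
        write_fasta_promoters(records, p)
        back = read_fasta_promoters(p)
        assert [(r.gene_id, r.sequence) for r in back] == [
            (r.gene_id, r.sequence) for r in records
        ]


def test_annotation_round_trip(tmp_path, sim_default):
    p = tmp_path / "ann.tsv"
    write_annotation(sim_default.annotation, p)
    back = read_annotation(p)
    assert back.term_genes == sim_default.annotation.term_genes


def test_normalization_idempotent():
    for raw in ["  hsa-miR-96 ", "HSA-MIR-96", "hsa-mir-96"]:
        once = normalize_mirna_id(raw)
        assert normalize_mirna_id(once) == once == "hsa-mir-96"
    assert normalize_gene_id(normalize_gene_id(" foxo1 ")) == "FOXO1"


def test_detection_from_pvalues():
    p = pd.DataFrame([[0.01, 0.2], [0.04999, 0.05]])
    out = detection_from_pvalues(p)
    assert out.to_numpy().tolist() == [[True, False], [True, False]]


def test_sim_outputs_pass_all_readers(tmp_path, sim_default):
    """Every generator-emitted file must satisfy its reader's validation."""
    write_sim_outputs(sim_default, tmp_path)
    mrna = read_expression_bundle(
        tmp_path / "mrna_values.tsv", tmp_path / "mrna_detection.tsv", tmp_path / "mrna_design.tsv"
    )
    mirna = read_expression_bundle(
        tmp_path / "mirna_values.tsv",
        tmp_path / "mirna_detection.tsv",
        tmp_path / "mirna_design.tsv",
        feature_kind="mirna",
    )
    tmap = read_target_pairs(tmp_path / "target_pairs.tsv", "planted")
    promoters = read_fasta_promoters(tmp_path / "promoters.fa")
    ann = read_annotation(tmp_path / "annotation.tsv")
    assert tmap.pairs == sim_default.target_map.pairs
    assert tmap.genes() <= set(mrna.feature_ids)
    assert tmap.mirnas() <= set(mirna.feature_ids)
    assert {r.gene_id for r in promoters} <= set(mrna.feature_ids)
    assert ann.annotated_genes() <= set(mrna.feature_ids)
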