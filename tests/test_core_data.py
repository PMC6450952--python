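"""Catalog I/O, genetic-support encoding, and observation flattening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetsafe.core_data import (
    SOC_LABELS,
    DrugRecord,
    GeneRecord,
    Support,
    build_observations,
    derive_genetic_support,
    load_drug_table,
    load_gene_table,
    load_observation_table,
    remove_common_side_effects,
    write_drug_table,
    write_gene_table,
    write_observation_table,
)
from targetsafe.synthetic import fixture_small


def test_vocabulary_is_fixed():
    assert len(SOC_LABELS) == 21
    assert len(set(SOC_LABELS)) == 21
    assert SOC_LABELS[0] == "Blood" and SOC_LABELS[-1] == "Vascular"


class TestGeneTable:
    def test_single_row_parse(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tmendelian_socs\tgwas_socs\tconstrained\t"
                     "expression_breadth\nG1\tHeart;Blood\t\t1\tenriched\n")
        cat = load_gene_table(p)
        assert set(cat) == {"G1"}
        assert cat["G1"].mendelian_socs == {"Heart", "Blood"}
        assert cat["G1"].gwas_socs == frozenset()
        assert cat["G1"].constrained

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tmendelian_socs\tgwas_socs\tconstrained\t"
                     "expression_breadth\n")
        assert load_gene_table(p) == {}

    @pytest.mark.parametrize("row,match", [
        ("G1\tCardiac\t\t0\tall", "Cardiac"),               # not in vocabulary
        ("G1\tHeart\t\t2\tall", "constrained"),
        ("G1\tHeart\t\t0\tbroad", "expression_breadth"),
    ])
    def test_bad_rows_rejected(self, tmp_path, row, match):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tmendelian_socs\tgwas_socs\tconstrained\t"
                     "expression_breadth\n" + row + "\n")
        with pytest.raises(ValueError, match=match):
            load_gene_table(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tmendelian_socs\tgwas_socs\tconstrained\t"
                     "expression_breadth\nG1\t\t\t0\tall\nG1\t\t\t0\tall\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_gene_table(p)


class TestDrugTable:
    def test_single_row_parse(self, tmp_path):
        p = tmp_path / "drugs.tsv"
        p.write_text("drug_id\ttargets\tmodality\troutes\tindications\t"
                     "side_effects\nD1\tG1;G2\tsmall_molecule\tenteral\t"
                     "Heart\tSkin;Heart\n")
        cat = load_drug_table(p)
        rec = cat["D1"]
        assert rec.targets == {"G1", "G2"}
        assert rec.indications == {"Heart"}
        assert rec.side_effects == {"Skin", "Heart"}

    def test_round_trip_identity(self, tmp_path):
        genes, drugs = fixture_small()
        gp, dp = tmp_path / "g.tsv", tmp_path / "d.tsv"
        write_gene_table(genes, gp)
        write_drug_table(drugs, dp)
        assert load_gene_table(gp) == genes
        assert load_drug_table(dp, load_gene_table(gp)) == drugs
        # byte-normalized round trip
        gp2, dp2 = tmp_path / "g2.tsv", tmp_path / "d2.tsv"
        write_gene_table(load_gene_table(gp), gp2)
        write_drug_table(load_drug_table(dp), dp2)
        assert gp.read_bytes() == gp2.read_bytes()
        assert dp.read_bytes() == dp2.read_bytes()

    @pytest.mark.parametrize("row,match", [
        ("D1\t\tsmall_molecule\tenteral\t\t", "no targets"),
        ("D1\tG1\tpeptide\tenteral\t\t", "modality"),
        ("D1\tG1\tsmall_molecule\toral\t\t", "route"),      # not a route group
    ])
    def test_bad_rows_rejected(self, tmp_path, row, match):
        p = tmp_path / "drugs.tsv"
        p.write_text("drug_id\ttargets\tmodality\troutes\tindications\t"
                     "side_effects\n" + row + "\n")
        with pytest.raises(ValueError, match=match):
            load_drug_table(p)


class TestGeneticSupport:
    def test_match_mismatch_no_info(self, small_catalogs):
        genes, drugs = small_catalogs
        assert derive_genetic_support(drugs["d1"], genes, "Heart",
                                      "mendelian") is Support.MATCH
        # d3 targets g2 (GWAS-informative) and g4 (blank)
        assert derive_genetic_support(drugs["d3"], genes, "Blood",
                                      "gwas") is Support.MISMATCH
        assert derive_genetic_support(drugs["d5"], genes, "Heart",
                                      "mendelian") is Support.NO_INFO

    def test_missing_gene_is_an_error(self, small_catalogs):
        genes, _ = small_catalogs
        ghost = DrugRecord("dx", frozenset({"g99"}))
        with pytest.raises(KeyError, match="g99"):
            derive_genetic_support(ghost, genes, "Heart", "mendelian")

    @given(soc=st.sampled_from(SOC_LABELS), extra=st.sampled_from(SOC_LABELS))
    def test_monotone_in_phenotypes(self, soc, extra):
        """Adding a phenotype SOC to a target gene never demotes support."""
        order = {Support.NO_INFO: 0, Support.MISMATCH: 1, Support.MATCH: 2}
        genes, drugs = fixture_small()
        for did, rec in drugs.items():
            gid = sorted(rec.targets)[0]
            before = derive_genetic_support(rec, genes, soc, "mendelian")
            grown = dict(genes)
            g = grown[gid]
            grown[gid] = GeneRecord(g.gene_id, g.mendelian_socs | {extra},
                                    g.gwas_socs, g.constrained,
                                    g.expression_breadth)
            after = derive_genetic_support(rec, grown, soc, "mendelian")
            assert order[after] >= order[before]


# hand-enumerated flags for fixture drug x SOC pairs
FIXTURE_FLAGS = [
    # drug, soc, on_ind, se, mend, gwas, any, all_info
    ("d1", "Heart", True, True, "MATCH", "NO_INFO", True, True),
    ("d1", "Skin", False, True, "MISMATCH", "NO_INFO", False, True),
    ("d2", "Blood", False, True, "MATCH", "NO_INFO", True, True),
    ("d3", "Heart", False, True, "NO_INFO", "MATCH", True, False),
    ("d3", "Blood", False, False, "NO_INFO", "MISMATCH", False, False),
    ("d4", "Mental", True, True, "MISMATCH", "MATCH", True, True),
    ("d5", "Infection", False, True, "NO_INFO", "NO_INFO", False, False),
    ("d6", "Immune", False, False, "MISMATCH", "MATCH", True, True),
]


class TestBuildObservations:
    def test_counts_and_mode(self, small_catalogs):
        genes, drugs = small_catalogs
        all_obs = build_observations(drugs, genes, "all")
        off = build_observations(drugs, genes, "off_indication")
        assert len(all_obs) == 21 * len(drugs)
        n_ind = sum(len(d.indications) for d in drugs.values())
        assert len(all_obs) - len(off) == n_ind
        assert not off.df["on_indication"].any()

    def test_off_indication_drops_the_indicated_soc(self, small_catalogs):
        genes, drugs = small_catalogs
        off = build_observations(drugs, genes, "off_indication")
        d1 = off.df[off.df.drug_id == "d1"]
        assert len(d1) == 20 and "Heart" not in set(d1.soc)

    @pytest.mark.parametrize(
        "drug,soc,on_ind,se,mend,gwas,any_s,all_info", FIXTURE_FLAGS)
    def test_hand_enumerated_flags(self, small_observations, drug, soc,
                                   on_ind, se, mend, gwas, any_s, all_info):
        df = small_observations.df
        row = df[(df.drug_id == drug) & (df.soc == soc)].iloc[0]
        assert (bool(row.on_indication), bool(row.side_effect), row.mendelian,
                row.gwas, bool(row.any_support),
                bool(row.all_targets_informative)) == (
                    on_ind, se, mend, gwas, any_s, all_info)

    def test_full_scale_observation_count(self):
        from targetsafe.synthetic import SimConfig, generate
        genes, drugs = generate(SimConfig(n_drugs=1819, n_genes=1046, seed=0))
        assert len(build_observations(drugs, genes)) == 38199


class TestObservationTable:
    def test_round_trip(self, small_observations, tmp_path):
        p = tmp_path / "obs.tsv"
        write_observation_table(small_observations, p)
        again = load_observation_table(p)
        pd.testing.assert_frame_equal(again.df, small_observations.df)


class TestRemoveCommonSideEffects:
    def test_frequent_term_removed(self):
        terms = {f"d{i}": {"headache"} if i < 6 else {"rash"} for i in range(10)}
        filtered, removed = remove_common_side_effects(
            [f"d{i}" for i in range(10)], terms, threshold=0.50)
        assert removed == ["headache"]
        assert filtered["d0"] == set()
        assert filtered["d9"] == {"rash"}

    def test_absent_term_changes_nothing(self):
        terms = {"d0": {"rash"}, "d1": set()}
        filtered, removed = remove_common_side_effects(["d0", "d1"], terms,
                                                       threshold=0.9)
        assert removed == []
        assert filtered == {"d0": {"rash"}, "d1": set()}

    def test_known_frequency_fixture(self):
        # 20 drugs x 5 terms; threshold 0.1 removes terms on >= 2 drugs
        counts = {"t1": 5, "t2": 2, "t3": 1, "t4": 0, "t5": 19}
        drug_ids = [f"d{i}" for i in range(20)]
        terms = {did: set() for did in drug_ids}
        for term, c in counts.items():
            for did in drug_ids[:c]:
                terms[did].add(term)
        _, removed = remove_common_side_effects(drug_ids, terms, threshold=0.10)
        assert removed == sorted(t for t, c in counts.items() if c >= 2)
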