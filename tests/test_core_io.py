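"""Bundle I/O round trips, validation errors, QC filters and the genus
collapse."""

import numpy as np
import pandas as pd
import pytest

from airway_biogeo.core_io import (PipelineConfig, TaxonomyMap, RANKS,
                                   apply_qc_filters, collapse_to_genus,
                                   derive_control_taxa, genus_name,
                                   load_dataset, parse_gg_lineage,
                                   read_counts_biom_json, read_counts_tsv,
                                   write_counts_biom_json, write_counts_tsv)
from airway_biogeo.simulate import write_dataset

from conftest import make_count_table


def _taxonomy(rows: dict) -> TaxonomyMap:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    frame.index.name = "taxon"
    return TaxonomyMap(frame.where(frame.notna(), None))


class TestCountTableValidation:
    def test_duplicate_subject_site_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_count_table(
                {"S1_BBa": {"A": 1}, "S1_BBb": {"A": 2}},
                [{"sample_id": "S1_BBa", "subject_id": "S1", "site": "BB",
                  "group": "AA"},
                 {"sample_id": "S1_BBb", "subject_id": "S1", "site": "BB",
                  "group": "AA"}])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_count_table(
                {"S1_BB": {"A": -1}},
                [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB",
                  "group": "AA"}])


class TestRoundTrips:
    def test_tsv_and_biom_identical(self, tmp_path, small_cohort):
        table = small_cohort[0]
        write_counts_tsv(table.counts, tmp_path / "c.tsv")
        write_counts_biom_json(table.counts, tmp_path / "c.biom.json")
        a = read_counts_tsv(tmp_path / "c.tsv")
        b = read_counts_biom_json(tmp_path / "c.biom.json")
        assert np.array_equal(a.values, table.counts.values)
        assert list(a.index) == list(b.index) == list(table.counts.index)
        assert np.array_equal(a.values, b.loc[a.index, a.columns].values)

    def test_full_bundle_round_trip(self, tmp_path, small_cohort):
        write_dataset(small_cohort, tmp_path / "bundle")
        table, tax, phy, clinical = load_dataset(
            tmp_path / "bundle" / "counts.tsv",
            tmp_path / "bundle" / "taxonomy.tsv",
            tmp_path / "bundle" / "tree.nwk",
            tmp_path / "bundle" / "metadata.tsv")
        orig = small_cohort[0]
        assert np.array_equal(table.counts.values, orig.counts.values)
        assert list(table.taxa) == list(orig.taxa)
        assert table.sample_meta["site"].equals(orig.sample_meta["site"])
        assert tax.lineage.equals(small_cohort[1].lineage)
        assert phy.tip_names == small_cohort[2].tip_names
        pd.testing.assert_frame_equal(
            clinical.values, small_cohort[3].values, check_dtype=False)
        pd.testing.assert_frame_equal(
            clinical.below_lod.astype(bool),
            small_cohort[3].below_lod.astype(bool))

    def test_biom_bundle_loads_identically(self, tmp_path, small_cohort):
        write_dataset(small_cohort, tmp_path / "t", counts_format="tsv")
        write_dataset(small_cohort, tmp_path / "b", counts_format="biom")
        bt = load_dataset(tmp_path / "t" / "counts.tsv",
                          tmp_path / "t" / "taxonomy.tsv",
                          tmp_path / "t" / "tree.nwk",
                          tmp_path / "t" / "metadata.tsv")
        bb = load_dataset(tmp_path / "b" / "counts.biom.json",
                          tmp_path / "b" / "taxonomy.tsv",
                          tmp_path / "b" / "tree.nwk",
                          tmp_path / "b" / "metadata.tsv")
        assert np.array_equal(bt[0].counts.values, bb[0].counts.values)
        assert bt[0].sample_ids == bb[0].sample_ids

    def test_missing_tree_taxon_named(self, tmp_path, small_cohort):
        import shutil
        write_dataset(small_cohort, tmp_path / "bundle")
        nwk = (tmp_path / "bundle" / "tree.nwk").read_text()
        first_taxon = small_cohort[0].taxa[0]
        # prune one tip crudely by renaming it in the newick text
        (tmp_path / "bundle" / "tree.nwk").write_text(
            nwk.replace(first_taxon, "RENAMED"))
        with pytest.raises(ValueError, match=first_taxon):
            load_dataset(tmp_path / "bundle" / "counts.tsv",
                         tmp_path / "bundle" / "taxonomy.tsv",
                         tmp_path / "bundle" / "tree.nwk",
                         tmp_path / "bundle" / "metadata.tsv")


class TestLineageParsing:
    def test_full_lineage(self):
        ranks = parse_gg_lineage(
            "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales;"
            " f__Prevotellaceae; g__Prevotella; s__")
        assert ranks[:6] == ["Bacteria", "Bacteroidetes", "Bacteroidia",
                             "Bacteroidales", "Prevotellaceae", "Prevotella"]
        assert ranks[6] is None

    def test_empty_payloads_unassigned(self):
        ranks = parse_gg_lineage("k__Bacteria; p__; c__; o__; f__; g__; s__")
        assert ranks[0] == "Bacteria" and all(r is None for r in ranks[1:])


class TestQcFilters:
    def _table(self):
        return make_count_table(
            {"S1_BB": {"A": 5, "B": 3, "C": 2},
             "S1_IS": {"A": 1, "B": 1, "C": 8},
             "S2_IS": {"A": 4, "B": 0, "C": 6},
             "NEG_BB": {"A": 0, "B": 2, "C": 0}},
            [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB",
              "group": "AA"},
             {"sample_id": "S1_IS", "subject_id": "S1", "site": "IS",
              "group": "AA", "squamous_pct": 0.85},
             {"sample_id": "S2_IS", "subject_id": "S2", "site": "IS",
              "group": "HC", "squamous_pct": 0.30},
             {"sample_id": "NEG_BB", "subject_id": "NEG", "site": "BB",
              "group": "HC", "is_control": True}])

    def test_control_taxa_removed_counts_unchanged(self):
        cfg = PipelineConfig()
        out = apply_qc_filters(self._table(), cfg, control_taxa={"B"})
        assert "B" not in out.taxa
        assert out.counts.loc["S1_BB", ["A", "C"]].tolist() == [5, 2]

    def test_squamous_is_sample_removed(self):
        out = apply_qc_filters(self._table(), PipelineConfig(), set())
        assert "S1_IS" not in out.sample_ids      # squamous 0.85 > 0.80
        assert "S2_IS" in out.sample_ids
        assert "NEG_BB" not in out.sample_ids     # control sample

    def test_identity_when_nothing_flagged(self):
        table = make_count_table(
            {"S1_BB": {"A": 5}},
            [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB",
              "group": "AA"}])
        out = apply_qc_filters(table, PipelineConfig(), set())
        assert out.counts.equals(table.counts)

    def test_idempotent(self):
        cfg = PipelineConfig()
        ctrl = derive_control_taxa(self._table())
        assert ctrl == {"B"}
        once = apply_qc_filters(self._table(), cfg, ctrl)
        twice = apply_qc_filters(once, cfg, set())
        assert once.counts.equals(twice.counts)

    def test_unknown_control_taxon_rejected(self):
        with pytest.raises(ValueError):
            apply_qc_filters(self._table(), PipelineConfig(), {"ZZZ"})


class TestGenusCollapse:
    def _inputs(self):
        table = make_count_table(
            {"S1_BB": {"o1": 5, "o2": 3, "o3": 2, "o4": 1},
             "S1_IS": {"o1": 1, "o2": 0, "o3": 4, "o4": 5}},
            [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB",
              "group": "AA"},
             {"sample_id": "S1_IS", "subject_id": "S1", "site": "IS",
              "group": "AA"}])
        tax = _taxonomy({
            "o1": ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                   "Prevotellaceae", "Prevotella", None],
            "o2": ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                   "Prevotellaceae", "Prevotella", None],
            "o3": ["Bacteria", "Proteobacteria", "Betaproteobacteria",
                   "Neisseriales", "Neisseriaceae", None, None],
            "o4": [None, None, None, None, None, None, None],
        })
        return table, tax

    def test_same_genus_summed(self):
        table, tax = self._inputs()
        out = collapse_to_genus(table, tax)
        assert out.counts.loc["S1_BB", "Prevotellaceae (Prevotella)"] == 8

    def test_family_level_fallback_label(self):
        table, tax = self._inputs()
        out = collapse_to_genus(table, tax)
        assert "Neisseriaceae" in out.taxa
        assert genus_name("Prevotellaceae (Prevotella)") == "Prevotella"
        assert genus_name("Neisseriaceae") == "Neisseriaceae"

    def test_unassigned_pools_to_unclassified(self):
        table, tax = self._inputs()
        out = collapse_to_genus(table, tax)
        assert out.counts.loc["S1_IS", "Unclassified"] == 5

    def test_per_sample_totals_conserved(self, small_cohort):
        table, tax = small_cohort[0], small_cohort[1]
        out = collapse_to_genus(table, tax)
        assert (out.counts.sum(axis=1).values
                == table.counts.sum(axis=1).values).all()

    def test_missing_taxonomy_rejected(self):
        table, tax = self._inputs()
        bad = TaxonomyMap(tax.lineage.drop(index="o4"))
        with pytest.raises(ValueError, match="o4"):
            collapse_to_genus(table, bad)


def test_config_toml_round_trip(tmp_path):
    (tmp_path / "cfg.toml").write_text(
        "rarefaction_depth = 500\nn_rarefactions = 4\nseed = 9\n"
        "fdr_q_assoc = 0.2\n")
    cfg = PipelineConfig.from_toml(tmp_path / "cfg.toml")
    assert cfg.rarefaction_depth == 500
    assert cfg.n_rarefactions == 4
    assert cfg.prevalence_genus_threshold == 0.03  # default preserved


def test_config_rejects_bad_thresholds():
    with pytest.raises(ValueError):
        PipelineConfig(squamous_max=1.5)
    with pytest.raises(ValueError):
        PipelineConfig(rarefaction_depth=0)
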