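"""Table parsing, validation, normalization and network round-trips."""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
import pytest

from adrepo import evidence_io
from adrepo.evidence_io import (PathwayGeneSets, ScoringConfig, read_drug_catalog,
                                read_evidence_bundle, read_gmt, read_network,
                                write_network)

GWAS_HEADER = "gene_symbol\tsnp_id\todds_ratio\tp_value\tinitial_n\treplication_n\tpubmed_id"


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestEvidenceBundle:
    def test_gwas_rows_parse_with_typed_odds_ratio(self, tmp_path):
        rows = "\n".join(f"G{i}\trs{i}\t1.22\t1e-6\t1000\t500\t123" for i in range(3))
        path = _write(tmp_path, "gwas.tsv", f"{GWAS_HEADER}\n{rows}\n")
        out = read_evidence_bundle({"genetics": path})["genetics"]
        assert len(out) == 3
        assert (out["odds_ratio"] == 1.22).all()
        assert out.attrs["rejected"] == []

    def test_dialect_stability_comma_vs_tab(self, tmp_path):
        content = [GWAS_HEADER.split("\t"), ["G1", "rs1", "1.3", "0.001", "10", "5", "1"]]
        tsv = _write(tmp_path, "a.tsv", "\n".join("\t".join(r) for r in content))
        csv = _write(tmp_path, "a.csv", "\n".join(",".join(r) for r in content))
        a = read_evidence_bundle({"genetics": tsv})["genetics"]
        b = read_evidence_bundle({"genetics": csv})["genetics"]
        pd.testing.assert_frame_equal(a, b)

    def test_header_only_file_gives_empty_table(self, tmp_path):
        path = _write(tmp_path, "gwas.tsv", GWAS_HEADER + "\n")
        out = read_evidence_bundle({"genetics": path})["genetics"]
        assert out.empty and list(out.columns)

    def test_missing_file_and_unknown_column_are_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_evidence_bundle({"genetics": tmp_path / "absent.tsv"})
        path = _write(tmp_path, "bad.tsv", GWAS_HEADER + "\tbogus\nG\trs1\t1.2\t0.01\t1\t1\t1\tx\n")
        with pytest.raises(ValueError, match="bogus"):
            read_evidence_bundle({"genetics": path})

    def test_invalid_rows_rejected_with_row_numbers(self, tmp_path):
        body = "G1\trs1\t1.2\t0.01\t1\t1\t1\nG2\trs2\t-0.5\t0.01\t1\t1\t1\nG3\trs3\t1.1\t2.0\t1\t1\t1\n"
        path = _write(tmp_path, "gwas.tsv", GWAS_HEADER + "\n" + body)
        out = read_evidence_bundle({"genetics": path})["genetics"]
        assert len(out) == 1
        lines = [line for line, _ in out.attrs["rejected"]]
        assert lines == [3, 4]  # 1-based file lines, header is line 1
        assert len(out) + len(out.attrs["rejected"]) == 3

    def test_duplicate_key_rows_keep_first(self, tmp_path):
        body = "G1\trs1\t1.2\t0.01\t1\t1\t1\nG1\trs1\t1.9\t0.01\t1\t1\t1\n"
        path = _write(tmp_path, "gwas.tsv", GWAS_HEADER + "\n" + body)
        out = read_evidence_bundle({"genetics": path})["genetics"]
        assert len(out) == 1 and out.loc[0, "odds_ratio"] == 1.2


class TestFoldNormalization:
    HEADER = "uniprot_id\tgene_symbol\tfold_change\tsample_type\tpubmed_id"

    def test_sub_unity_ratio_becomes_negative_reciprocal(self, tmp_path):
        path = _write(tmp_path, "prot.tsv", f"{self.HEADER}\nP1\tG1\t0.5\tCSF\t1\n")
        out = read_evidence_bundle({"proteomics": path})["proteomics"]
        assert out.loc[0, "fold_change"] == -2.0
        assert out.attrs["n_normalized"] == 1

    def test_sub_unity_ratio_rejected_without_normalization(self, tmp_path):
        path = _write(tmp_path, "prot.tsv", f"{self.HEADER}\nP1\tG1\t0.5\tCSF\t1\n")
        out = read_evidence_bundle({"proteomics": path}, auto_normalize=False)["proteomics"]
        assert out.empty and len(out.attrs["rejected"]) == 1

    def test_zero_fold_change_always_rejected(self, tmp_path):
        path = _write(tmp_path, "prot.tsv", f"{self.HEADER}\nP1\tG1\t0\tCSF\t1\n")
        out = read_evidence_bundle({"proteomics": path})["proteomics"]
        assert out.empty and len(out.attrs["rejected"]) == 1


class TestDrugCatalog:
    HEADER = "drug_name\ttarget_uniprot\tstage\tmode_of_action\toriginal_indication\tsource_db"

    def test_stage_synonyms_and_fallback(self, tmp_path, caplog):
        body = ("d1\tP1\tApproved\tinhibitor\tx\tTTD\n"
                "d2\tP1\tPhase I/II\tagonist\tx\tTTD\n"
                "d3\tP1\tPreclinical\tinhibitor\tx\tTTD\n")
        path = _write(tmp_path, "drugs.tsv", self.HEADER + "\n" + body)
        with caplog.at_level(logging.WARNING):
            out = read_drug_catalog(path)
        assert list(out["stage"]) == ["approved", "clinical_trial", "experimental"]
        assert out.attrs["n_stage_fallback"] == 1
        assert "Preclinical" in caplog.text

    def test_unknown_mode_of_action_falls_back_to_unknown(self, tmp_path):
        path = _write(tmp_path, "drugs.tsv", self.HEADER + "\nd1\tP1\tApproved\tzapper\tx\tTTD\n")
        out = read_drug_catalog(path)
        assert out.loc[0, "mode_of_action"] == "unknown"
        assert out.attrs["n_mode_fallback"] == 1

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = _write(tmp_path, "drugs.tsv", "drug_name\tstage\nd1\tApproved\n")
        with pytest.raises(ValueError, match="target_uniprot"):
            read_drug_catalog(path)


class TestGmt:
    def test_universe_is_union_of_sets(self, tmp_path):
        text = ("set1\tdesc\ta\tb\tc\n"
                "set2\tdesc\tc\td\te\tf\tg\n")
        sets = read_gmt(_write(tmp_path, "p.gmt", text))
        assert len(sets.universe) == 7
        assert sets.sets["set1"] == {"a", "b", "c"}

    def test_single_set(self, tmp_path):
        sets = read_gmt(_write(tmp_path, "p.gmt", "only\td\tA\tB\n"))
        assert sets.universe == {"A", "B"}

    def test_malformed_line_names_line_number(self, tmp_path):
        path = _write(tmp_path, "p.gmt", "ok\td\ta\tb\nbroken\td\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_pathway_outside_explicit_universe_is_restricted(self, tmp_path):
        path = _write(tmp_path, "p.gmt", "s\td\ta\tb\tz\n")
        sets = read_gmt(path, universe={"a", "b", "c"})
        assert sets.sets["s"] == {"a", "b"}

    def test_gene_sets_invariants(self):
        with pytest.raises(ValueError):
            PathwayGeneSets(sets={"s": frozenset()}, universe=frozenset({"a"}))
        with pytest.raises(ValueError, match="outside"):
            PathwayGeneSets(sets={"s": frozenset({"x"})}, universe=frozenset({"a"}))


class TestNetworkIO:
    def _graph(self):
        g = nx.Graph()
        g.add_node("HMDB1", kind="metabolite")
        g.add_node("P1", kind="protein")
        g.add_edge("HMDB1", "P1")
        return g

    def test_single_edge_sif(self, tmp_path):
        path = tmp_path / "net.sif"
        write_network(self._graph(), path, "SIF")
        assert path.read_text().splitlines() == ["HMDB1\tlinks\tP1"]

    def test_graphml_roundtrip_preserves_structure_and_attributes(self, tmp_path):
        g = self._graph()
        g.add_node("P2", kind="protein")  # isolated
        path = tmp_path / "net.graphml"
        write_network(g, path, "GraphML")
        back = read_network(path, "GraphML")
        assert nx.is_isomorphic(g, back)
        assert back.nodes["HMDB1"]["kind"] == "metabolite"

    def test_sif_roundtrip(self, tmp_path):
        path = tmp_path / "net.sif"
        write_network(self._graph(), path, "SIF")
        back = read_network(path, "SIF")
        assert set(back.edges) == {("HMDB1", "P1")}

    def test_empty_graph(self, tmp_path):
        write_network(nx.Graph(), tmp_path / "e.sif", "SIF")
        assert (tmp_path / "e.sif").read_text() == ""
        write_network(nx.Graph(), tmp_path / "e.graphml", "GraphML")
        assert read_network(tmp_path / "e.graphml", "GraphML").number_of_nodes() == 0

    def test_unknown_format_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_network(nx.Graph(), tmp_path / "x", "dot")


class TestScoringConfig:
    def test_defaults_and_yaml_roundtrip(self, tmp_path):
        cfg = ScoringConfig()
        assert (cfg.w_effect, cfg.w_citation, cfg.w_publication) == (0.33, 0.34, 0.33)
        assert (cfg.f_ref, cfg.or_ref, cfg.c_ref, cfg.h_ref) == (2.37, 3.7, 4092, 11294)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ScoringConfig.from_yaml(path) == cfg

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScoringConfig(w_effect=0.5, w_citation=0.5, w_publication=0.5)
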