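import numpy as np
import networkx as nx
import pytest

from transpred import AA_ALPHABET
from transpred.go_dataset import (
    DatasetConfig,
    GoAnnotation,
    LabeledDataset,
    assemble_labeled_dataset,
    filter_annotations,
    pairwise_identity,
    parse_gaf,
    parse_obo,
    propagate_annotations,
    reduce_redundancy,
)
from transpred.seq_io import ProteinRecord
from transpred.synthetic import DEMO_GAF_ROWS, write_demo_gaf, write_demo_obo


@pytest.fixture(scope="module")
def demo_graph(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "demo.obo"
    write_demo_obo(path)
    return parse_obo(path)


class TestParseObo:
    def test_chain_fixture(self, tmp_path):
        path = tmp_path / "chain.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2 ! b\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:3 ! c\n\n"
            "[Term]\nid: GO:3\nname: c\n"
        )
        graph = parse_obo(path)
        is_a = graph.is_a_subgraph()
        assert is_a.number_of_edges() == 2
        assert graph.ancestors("GO:1") == {"GO:2", "GO:3"}

    def test_obsolete_excluded(self, demo_graph):
        assert "GO:0000012" not in demo_graph.terms

    def test_part_of_not_used_for_propagation(self, demo_graph):
        # GO:0000007 is_a GO:0000006, plus a part_of edge to the root:
        # the part_of edge must not shortcut the is_a closure
        edge_types = {
            d["type"] for _, _, d in demo_graph.graph.edges("GO:0000007", data=True)
        }
        assert "other" in edge_types
        assert demo_graph.ancestors("GO:0000007") == {
            "GO:0000006", "GO:0000004", "GO:0000001",
        }

    def test_namespace_recorded(self, demo_graph):
        assert demo_graph.namespace("GO:0000001") == "molecular_function"


class TestParseGaf:
    def test_fixture_round_trip(self, tmp_path):
        path = tmp_path / "demo.gaf"
        write_demo_gaf(path)
        annotations = parse_gaf(path)
        assert len(annotations) == len(DEMO_GAF_ROWS)
        assert annotations[0].accession == "P00001"
        assert annotations[0].term == "GO:0000005"
        assert annotations[0].evidence_code == "IDA"

    def test_comments_skipped(self, tmp_path):
        path = tmp_path / "c.gaf"
        path.write_text("!gaf-version: 2.2\n! comment\n")
        assert parse_gaf(path) == []


class TestFilterAnnotations:
    def test_iea_removed(self):
        anns = [GoAnnotation("P1", "GO:1", evidence_code="IEA")]
        assert filter_annotations(anns) == []

    def test_ida_kept(self):
        anns = [GoAnnotation("P1", "GO:1", evidence_code="IDA")]
        assert filter_annotations(anns) == anns

    def test_negated_removed(self):
        anns = [GoAnnotation("P1", "GO:1", evidence_code="IDA", qualifier="NOT|enables")]
        assert filter_annotations(anns) == []


class TestPropagateAnnotations:
    def test_chain(self, demo_graph):
        anns = [GoAnnotation("P1", "GO:0000007")]
        out = propagate_annotations(anns, demo_graph)
        terms = {a.term for a in out}
        assert terms == {"GO:0000007", "GO:0000006", "GO:0000004", "GO:0000001"}

    def test_root_unchanged(self, demo_graph):
        out = propagate_annotations([GoAnnotation("P1", "GO:0000001")], demo_graph)
        assert {a.term for a in out} == {"GO:0000001"}

    def test_diamond_matches_matrix_power_oracle(self, demo_graph):
        # brute-force reachability via boolean matrix powers
        is_a = demo_graph.is_a_subgraph()
        nodes = sorted(is_a.nodes)
        idx = {t: i for i, t in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for u, v in is_a.edges:
            A[idx[u], idx[v]] = True
        closure = A.copy()
        for _ in range(len(nodes)):
            closure = closure | (closure @ A)
        for term in ["GO:0000005", "GO:0000009", "GO:0000007"]:
            out = propagate_annotations([GoAnnotation("P1", term)], demo_graph)
            expected = {nodes[j] for j in range(len(nodes)) if closure[idx[term], j]}
            assert {a.term for a in out} == expected | {term}

    def test_unknown_term_skipped(self, demo_graph, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = propagate_annotations([GoAnnotation("P1", "GO:0000099")], demo_graph)
        assert out == []
        assert "unknown term" in caplog.text

    def test_idempotent(self, demo_graph):
        anns = [GoAnnotation("P1", "GO:0000005"), GoAnnotation("P2", "GO:0000011")]
        once = propagate_annotations(anns, demo_graph)
        twice = propagate_annotations(once, demo_graph)
        assert {(a.accession, a.term) for a in once} == {
            (a.accession, a.term) for a in twice
        }

    def test_monotone(self, demo_graph):
        base = [GoAnnotation("P1", "GO:0000006")]
        more = base + [GoAnnotation("P1", "GO:0000005")]
        small = {(a.accession, a.term) for a in propagate_annotations(base, demo_graph)}
        large = {(a.accession, a.term) for a in propagate_annotations(more, demo_graph)}
        assert small <= large

    def test_faulty_edge_scenario(self, demo_graph):
        # the channel term sits (wrongly) under amino-acid transport, so a
        # channel protein is propagated into the transporter class;
        # consensus outlier detection is the downstream mitigation
        out = propagate_annotations([GoAnnotation("P00005", "GO:0000009")], demo_graph)
        assert "GO:0000002" in {a.term for a in out}


def _config():
    return DatasetConfig(
        class_terms={"amino_acid": "GO:0000002", "sugar": "GO:0000004"}
    )


class TestAssembleLabeledDataset:
    def _pipeline(self, demo_graph, proteins):
        anns = [
            GoAnnotation(acc, term, evidence_code=ev, qualifier=q)
            for acc, term, q, ev in DEMO_GAF_ROWS
        ]
        anns = filter_annotations(anns)
        anns = propagate_annotations(anns, demo_graph)
        return assemble_labeled_dataset(proteins, anns, _config())

    def test_fixture_counts(self, demo_graph):
        rng = np.random.default_rng(0)

        def seq(n=30):
            return "".join(rng.choice(list(AA_ALPHABET), size=n))

        proteins = [
            ProteinRecord(f"P{i:05d}", seq()) for i in range(1, 14)
        ]
        proteins.append(ProteinRecord("P00014", seq(), fragment=True))
        proteins.append(ProteinRecord("P00015", seq() + "X"))
        proteins.append(ProteinRecord("P00016", seq()))
        proteins.append(ProteinRecord("P00017", seq()))
        proteins.append(ProteinRecord("P00018", seq()))
        ds = self._pipeline(demo_graph, proteins)
        kept = set(ds.accessions())
        # P00011 (IEA only), P00012 (negated), P00018 (unknown term) -> unlabeled
        assert {"P00011", "P00012", "P00018"}.isdisjoint(kept)
        assert ds.exclusion_counts["multilabel"] == 1      # P00013
        assert ds.exclusion_counts["fragment"] == 1        # P00014
        assert ds.exclusion_counts["nonstandard_residues"] == 1  # P00015
        # labels via propagation: P00001/P00016 (acidic aa), P00006 (glucose), ...
        assert ds.label_counts == {"amino_acid": 6, "sugar": 6}

    def test_descendant_label_via_propagation(self, demo_graph):
        anns = propagate_annotations(
            [GoAnnotation("P1", "GO:0000007"), GoAnnotation("P2", "GO:0000010")],
            demo_graph,
        )
        rng = np.random.default_rng(1)
        proteins = [
            ProteinRecord("P1", "".join(rng.choice(list(AA_ALPHABET), size=25))),
            ProteinRecord("P2", "".join(rng.choice(list(AA_ALPHABET), size=25))),
        ]
        ds = assemble_labeled_dataset(proteins, anns, _config())
        assert dict(ds.samples) == {"P1": "sugar", "P2": "amino_acid"}

    def test_empty_class_is_error(self, demo_graph):
        anns = propagate_annotations([GoAnnotation("P1", "GO:0000007")], demo_graph)
        proteins = [ProteinRecord("P1", "ACDEF")]
        with pytest.raises(ValueError, match="zero members"):
            assemble_labeled_dataset(proteins, anns, _config())


class TestReduceRedundancy:
    def _dataset(self, accs, label="a"):
        return LabeledDataset(samples=[(acc, label) for acc in accs])

    def test_identical_pair_one_retained(self):
        seqs = {"A": "ACDEFGHIKL", "B": "ACDEFGHIKL"}
        out = reduce_redundancy(self._dataset(["A", "B"]), seqs)
        assert len(out.samples) == 1

    def test_dissimilar_pair_both_retained(self):
        seqs = {"A": "ACDEFGHIKLMNPQRSTVWY", "B": "YWVTSRQPNMLKIHGFEDCA"}
        assert pairwise_identity(seqs["A"], seqs["B"]) < 0.70
        out = reduce_redundancy(self._dataset(["A", "B"]), seqs)
        assert len(out.samples) == 2

    def test_mutated_family_fixture(self):
        # 20 mutated copies of 3 seed sequences; after reduction no
        # retained pair may reach the threshold (brute-force check)
        rng = np.random.default_rng(11)
        alphabet = list(AA_ALPHABET)
        seeds = ["".join(rng.choice(alphabet, size=60)) for _ in range(3)]
        seqs = {}
        for i in range(20):
            base = list(seeds[i % 3])
            for pos in rng.choice(60, size=6, replace=False):
                base[pos] = rng.choice(alphabet)
            seqs[f"M{i:02d}"] = "".join(base)
        out = reduce_redundancy(self._dataset(sorted(seqs)), seqs, threshold=0.70)
        kept = out.accessions()
        assert set(kept) <= set(seqs)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert pairwise_identity(seqs[a], seqs[b]) < 0.70

    def test_output_subset_of_input(self):
        seqs = {"A": "ACDEF", "B": "ACDEF", "C": "KLMNP"}
        out = reduce_redundancy(self._dataset(["A", "B", "C"]), seqs)
        assert set(out.accessions()) <= {"A", "B", "C"}

    def test_per_class_clustering(self):
        # identical sequences in different classes are both kept
        seqs = {"A": "ACDEFGHIKL", "B": "ACDEFGHIKL"}
        ds = LabeledDataset(samples=[("A", "x"), ("B", "y")])
        out = reduce_redundancy(ds, seqs)
        assert len(out.samples) == 2


class TestLabeledDatasetIo:
    def test_tsv_round_trip(self, tmp_path):
        ds = LabeledDataset(samples=[("A", "x"), ("B", "y")])
        p = tmp_path / "ds.tsv"
        ds.to_tsv(p)
        assert LabeledDataset.from_tsv(p).samples == ds.samples
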