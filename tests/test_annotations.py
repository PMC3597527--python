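import datetime as dt
import itertools

import numpy as np
import pytest

from fktransfer.analogs import AnalogMap, AnalogScore
from fktransfer.annotations import (
    Annotation,
    AnnotationSet,
    assemble_training_sets,
    filter_experimental,
    propagate,
    transfer,
    transfer_sequence_only,
)
from fktransfer.errors import UntrainableTermError
from fktransfer.ontology import OntologyDAG

D = dt.date(2009, 3, 2)


def ann(gene, term, evidence="IDA", qualifier="", organism="org",
        provenance="direct", source_gene=None, date=D):
    return Annotation(gene=gene, organism=organism, term=term, evidence=evidence,
                      qualifier=qualifier, provenance=provenance,
                      source_gene=source_gene, date=date)


def analog_map(*pairs):
    scores = [
        AnalogScore(a, oa, b, ob, k=5, m=5, n=5, n_background=100, p=1e-6)
        for a, oa, b, ob in pairs
    ]
    return AnalogMap(pairs=scores, cutoff=0.01)


class TestFilterExperimental:
    def test_iea_dropped(self):
        out = filter_experimental(AnnotationSet([ann("g", "t", evidence="IEA")]))
        assert len(out) == 0

    def test_not_qualifier_dropped(self):
        out = filter_experimental(AnnotationSet([ann("g", "t", qualifier="NOT")]))
        assert len(out) == 0

    def test_compound_not_qualifier_dropped(self):
        out = filter_experimental(
            AnnotationSet([ann("g", "t", qualifier="NOT|contributes_to")])
        )
        assert len(out) == 0

    def test_all_six_codes_kept(self):
        records = [ann("g", "t", evidence=c) for c in
                   ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP")]
        assert len(filter_experimental(AnnotationSet(records))) == 6

    def test_empty_input(self):
        assert len(filter_experimental(AnnotationSet())) == 0


class TestPropagate:
    def test_child_implies_parent(self):
        dag = OntologyDAG({"child": {"parent"}, "parent": set()})
        out = propagate(AnnotationSet([ann("g", "child")]), dag)
        assert out.gene_terms("g") == {"child", "parent"}

    def test_diamond_collapses_to_single_record(self, diamond_dag):
        out = propagate(AnnotationSet([ann("g", "child")]), diamond_dag)
        assert sum(1 for r in out if r.term == "root") == 1

    def test_root_annotation_unchanged(self):
        dag = OntologyDAG({"t": {"root"}, "root": set()})
        out = propagate(AnnotationSet([ann("g", "root")]), dag)
        assert out.gene_terms("g") == {"root"}

    def test_missing_term_is_hard_error(self):
        dag = OntologyDAG({"t": set()})
        with pytest.raises(KeyError, match="ghost"):
            propagate(AnnotationSet([ann("g", "ghost")]), dag)

    def test_duplicate_keeps_earliest_date(self):
        dag = OntologyDAG({"a": {"p"}, "b": {"p"}, "p": set()})
        early, late = dt.date(2005, 1, 1), dt.date(2009, 1, 1)
        out = propagate(
            AnnotationSet([ann("g", "a", date=late), ann("g", "b", date=early)]), dag
        )
        rec = [r for r in out if r.term == "p"]
        assert len(rec) == 1 and rec[0].date == early


class TestTransfer:
    def test_pairwise_union_with_provenance(self):
        anns = AnnotationSet(
            [ann("a", "t1"), ann("a", "t2"), ann("b", "t2", organism="org2"),
             ann("b", "t3", organism="org2")]
        )
        out = transfer(anns, analog_map(("a", "org", "b", "org2")))
        assert out.gene_terms("a") == {"t1", "t2", "t3"}
        assert out.gene_terms("b") == {"t1", "t2", "t3"}
        b_t1 = [r for r in out if r.gene == "b" and r.term == "t1"]
        assert b_t1[0].provenance == "transferred"
        assert b_t1[0].source_gene == "a"
        assert b_t1[0].date == D  # inherits the source record's date

    def test_gene_without_analogs_unchanged(self):
        anns = AnnotationSet([ann("a", "t1")])
        out = transfer(anns, analog_map(("x", "org", "y", "org2")))
        assert len(out) == len(anns)

    def test_one_hop_no_chaining(self):
        anns = AnnotationSet([ann("a", "tA"), ann("b", "tB", organism="org2"),
                              ann("c", "tC", organism="org3")])
        amap = analog_map(("a", "org", "b", "org2"), ("b", "org2", "c", "org3"))
        out = transfer(anns, amap)
        assert "tA" not in out.gene_terms("c")  # a's term does not reach c via b
        assert "tB" in out.gene_terms("c")

    def test_idempotent(self):
        anns = AnnotationSet([ann("a", "t1"), ann("b", "t2", organism="org2")])
        amap = analog_map(("a", "org", "b", "org2"))
        once = transfer(anns, amap)
        twice = transfer(once, amap)
        assert len(twice) == len(once)
        assert {(r.gene, r.term, r.provenance) for r in twice} == {
            (r.gene, r.term, r.provenance) for r in once
        }

    def test_never_removes_annotations(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        anns = AnnotationSet(
            [ann(g, f"t{int(rng.integers(4))}") for g in genes for _ in range(2)]
        )
        amap = analog_map(("g0", "org", "g5", "org"), ("g1", "org", "g6", "org"))
        out = transfer(anns, amap)
        assert len(out) >= len(anns)

    def test_transferred_traceable_to_direct_source(self):
        anns = AnnotationSet([ann("a", "t1"), ann("b", "t2", organism="org2")])
        out = transfer(anns, analog_map(("a", "org", "b", "org2")))
        direct_pairs = {(r.gene, r.term) for r in anns}
        for r in out:
            if r.provenance == "transferred":
                assert (r.source_gene, r.term) in direct_pairs


class TestSequenceOnlyTransfer:
    def test_transfers_regardless_of_function(self):
        anns = AnnotationSet([ann("a", "t1")])
        out = transfer_sequence_only(anns, [("a", "org", "b", "org2")])
        assert "t1" in out.gene_terms("b")

    def test_equivalent_to_fkt_when_pair_sets_match(self):
        anns = AnnotationSet([ann("a", "t1"), ann("b", "t2", organism="org2")])
        via_fkt = transfer(anns, analog_map(("a", "org", "b", "org2")))
        via_seq = transfer_sequence_only(anns, [("a", "org", "b", "org2")])
        assert {(r.gene, r.term) for r in via_fkt} == {(r.gene, r.term) for r in via_seq}

    def test_empty_rbh_list_unchanged(self):
        anns = AnnotationSet([ann("a", "t1")])
        assert len(transfer_sequence_only(anns, [])) == 1


class TestPropagateTransferCommute:
    def test_commutes_on_random_small_dags(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n_terms = int(rng.integers(3, 7))
            terms = [f"T{i}" for i in range(n_terms)]
            parents = {t: set() for t in terms}
            for i, t in enumerate(terms[1:], start=1):
                for j in range(i):
                    if rng.random() < 0.4:
                        parents[t].add(terms[j])
            dag = OntologyDAG(parents)
            anns = AnnotationSet(
                [ann(g, terms[int(rng.integers(n_terms))], organism="org")
                 for g in ("a", "b") for _ in range(2)]
            )
            amap = analog_map(("a", "org", "b", "org2"))
            route1 = propagate(transfer(anns, amap), dag)
            route2 = transfer(propagate(anns, dag), amap)
            # brute-force closure oracle: ancestor closure of the unioned term sets
            for g in ("a", "b"):
                direct = set(anns.gene_terms("a")) | set(anns.gene_terms("b"))
                closure = set(direct)
                for t in direct:
                    closure |= dag.ancestors(t)
                assert set(route1.gene_terms(g)) == closure
                assert set(route2.gene_terms(g)) == closure


class TestTrainingSets:
    DAG = OntologyDAG({"t": {"root"}, "t_child": {"t"}, "other": {"root"},
                       "root": set()})
    UNI = frozenset({"g1", "g2", "g3", "g4", "g5"})

    def test_transferred_only_positives_trainable(self):
        anns = AnnotationSet(
            [ann("g1", "t", provenance="transferred", source_gene="src"),
             ann("g2", "t", provenance="transferred", source_gene="src")]
        )
        ts = assemble_training_sets("t", anns, self.UNI, self.DAG)
        assert ts.positives == {"g1", "g2"}

    def test_descendant_annotation_excluded_from_negatives(self):
        anns = AnnotationSet([ann("g1", "t"), ann("g2", "t_child")])
        ts = assemble_training_sets("t", anns, self.UNI, self.DAG)
        assert "g2" not in ts.negatives and "g2" not in ts.positives

    def test_unannotated_universe_gene_is_negative(self):
        anns = AnnotationSet([ann("g1", "t"), ann("g3", "other")])
        ts = assemble_training_sets("t", anns, self.UNI, self.DAG)
        assert "g5" in ts.negatives
        assert "g3" in ts.negatives  # unrelated term does not exclude

    def test_zero_positives_raises(self):
        with pytest.raises(UntrainableTermError):
            assemble_training_sets("t", AnnotationSet(), self.UNI, self.DAG)

    def test_exclusion_terms_respected(self):
        anns = AnnotationSet([ann("g1", "t"), ann("g4", "other")])
        ts = assemble_training_sets("t", anns, self.UNI, self.DAG,
                                    exclusion_terms=["other"])
        assert "g4" not in ts.negatives
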