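"""Ontology parsing, annotation propagation, hypergeometric scoring."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualsens import (
    GoDag,
    SynthConfig,
    enrich_genes,
    filter_terms,
    generate_ontology,
    hypergeom_p,
    parse_annotations,
    parse_obo,
    propagate,
)
from dualsens.enrich import AnnotationSet, OboFormatError
from dualsens.synth import write_annotations, write_gaf, write_obo

MINIMAL_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
is_a: GO:0000001 ! biological_process
"""


def chain_dag(*terms):
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parent in zip(terms[1:], terms):
        g.add_edge(child, parent)
    return GoDag(g, terms[0], {t: t for t in terms})


def enumeration_tail(x, k, m, n):
    """P(X >= x) by exhaustive enumeration of all k-subsets of n genes."""
    hits = total = 0
    for pick in itertools.combinations(range(n), k):
        total += 1
        if sum(1 for i in pick if i < m) >= x:
            hits += 1
    return hits / total


class TestParseObo:
    def test_minimal_two_term_file(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text(MINIMAL_OBO)
        dag = parse_obo(path)
        assert dag.root == "GO:0000001"
        assert dag.terms == {"GO:0000001", "GO:0000002"}
        assert dag.ancestors("GO:0000002") == {"GO:0000001"}

    def test_obsolete_terms_excluded(self, tmp_path):
        obo = MINIMAL_OBO + (
            "\n[Term]\nid: GO:0000003\nname: dead process\n"
            "namespace: biological_process\nis_obsolete: true\n"
            "is_a: GO:0000001 ! biological_process\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(obo)
        assert "GO:0000003" not in parse_obo(path).terms

    def test_other_namespaces_dropped(self, tmp_path):
        obo = MINIMAL_OBO + (
            "\n[Term]\nid: GO:0000004\nname: some component\n"
            "namespace: cellular_component\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(obo)
        assert "GO:0000004" not in parse_obo(path).terms

    def test_round_trip_with_generator_emitter(self, tmp_path):
        cfg = SynthConfig(n_genes=30, seed=17)
        dag, _ = generate_ontology(40, 30, cfg)
        path = tmp_path / "synth.obo"
        write_obo(dag, path)
        parsed = parse_obo(path)
        assert parsed.root == dag.root
        assert set(parsed.graph.edges) == set(dag.graph.edges)
        assert parsed.names == dag.names

    def test_cycle_is_format_error(self, tmp_path):
        obo = MINIMAL_OBO + "is_a: GO:0000002 ! self\n"
        # make the root point back at the child
        obo = obo.replace(
            "name: biological_process\nnamespace: biological_process\n",
            "name: biological_process\nnamespace: biological_process\n"
            "is_a: GO:0000002 ! child process\n",
            1,
        )
        path = tmp_path / "go.obo"
        path.write_text(obo)
        with pytest.raises(OboFormatError):
            parse_obo(path)


class TestParseAnnotations:
    def test_gaf_not_qualifier_excluded(self, tmp_path):
        direct = {"geneA": {"GO:0000002"}, "geneB": {"GO:0000002"}}
        path = tmp_path / "ann.gaf"
        write_gaf(direct, path)
        lines = path.read_text().splitlines()
        lines[1] = lines[1].replace("involved_in", "NOT|involved_in")
        path.write_text("\n".join(lines) + "\n")
        parsed = parse_annotations(path, "gaf")
        assert "geneA" not in parsed
        assert parsed["geneB"] == {"GO:0000002"}

    def test_duplicate_pairs_collapse(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("geneA\tGO:0000002\ngeneA\tGO:0000002\n")
        parsed = parse_annotations(path, "two_column")
        assert parsed == {"geneA": frozenset({"GO:0000002"})}

    def test_gaf_and_two_column_agree(self, tmp_path):
        cfg = SynthConfig(n_genes=25, seed=18)
        dag, direct = generate_ontology(20, 25, cfg)
        gaf, tsv = tmp_path / "a.gaf", tmp_path / "a.tsv"
        write_gaf(direct, gaf)
        write_annotations(direct, tsv)
        from_gaf = parse_annotations(gaf, "gaf")
        from_tsv = parse_annotations(tsv, "two_column")
        assert from_gaf == from_tsv
        a = propagate(dag, from_gaf)
        b = propagate(dag, from_tsv)
        assert a.closure == b.closure

    def test_malformed_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.gaf"
        path.write_text("A\tB\tC\n")
        with pytest.raises(ValueError):
            parse_annotations(path, "gaf")


class TestPropagate:
    def test_chain_closure(self):
        dag = chain_dag("root", "A", "B")
        ann = propagate(dag, {"g": {"B"}})
        assert ann.closure["g"] == {"B", "A", "root"}

    def test_diamond_counts_each_ancestor_once(self):
        g = nx.DiGraph()
        g.add_edges_from([("leaf", "L"), ("leaf", "R"), ("L", "root"), ("R", "root")])
        dag = GoDag(g, "root")
        ann = propagate(dag, {"g": {"leaf"}})
        assert ann.closure["g"] == {"leaf", "L", "R", "root"}
        assert ann.term_genes["root"] == {"g"}

    def test_matches_transitive_closure_matrix_oracle(self):
        cfg = SynthConfig(n_genes=40, seed=19)
        dag, direct = generate_ontology(50, 40, cfg)
        terms = sorted(dag.graph.nodes)
        idx = {t: i for i, t in enumerate(terms)}
        adj = np.zeros((len(terms), len(terms)), dtype=bool)
        for child, parent in dag.graph.edges:
            adj[idx[child], idx[parent]] = True
        reach = adj.copy()
        for _ in range(len(terms)):
            new = reach | (reach @ adj)
            if (new == reach).all():
                break
            reach = new
        ann = propagate(dag, direct)
        for gene, terms_direct in direct.items():
            expect = set(terms_direct)
            for t in terms_direct:
                expect |= {terms[j] for j in np.flatnonzero(reach[idx[t]])}
            assert ann.closure[gene] == expect

    def test_idempotent(self):
        cfg = SynthConfig(n_genes=30, seed=23)
        dag, direct = generate_ontology(30, 30, cfg)
        once = propagate(dag, direct)
        twice = propagate(dag, {g: set(ts) for g, ts in once.closure.items()})
        assert once.closure == twice.closure

    def test_parent_counts_dominate_child_counts(self):
        cfg = SynthConfig(n_genes=60, seed=24)
        dag, direct = generate_ontology(40, 60, cfg)
        ann = propagate(dag, direct)
        counts = ann.term_counts()
        for child, parent in dag.graph.edges:
            assert counts.get(parent, 0) >= counts.get(child, 0)

    def test_unknown_terms_reported_and_dropped(self):
        dag = chain_dag("root", "A")
        with pytest.warns(UserWarning):
            ann = propagate(dag, {"g": {"A", "GHOST"}})
        assert ann.direct["g"] == {"A"}


class TestFilterTerms:
    def make_ann(self, sizes):
        term_genes = {
            t: frozenset(f"g{i}" for i in range(c)) for t, c in sizes.items()
        }
        return AnnotationSet({}, {}, term_genes)

    def test_strict_bounds(self):
        ann = self.make_ann({"t5": 5, "t6": 6, "t299": 299, "t300": 300})
        assert filter_terms(ann) == {"t6", "t299"}

    def test_root_removed_by_high_frequency_filter(self):
        ann = self.make_ann({"root": 500, "small": 10})
        assert "root" not in filter_terms(ann)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_terms(self.make_ann({}), 300, 5)


class TestHypergeomP:
    def test_zero_selected_is_certain(self):
        assert hypergeom_p(0, 4, 5, 10) == 1.0

    def test_hand_enumerated_example(self):
        # all 4 drawn from the 5 annotated among 10: C(5,4)/C(10,4) = 5/210
        assert hypergeom_p(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-12)
        assert hypergeom_p(4, 4, 5, 10) == pytest.approx(
            enumeration_tail(4, 4, 5, 10), abs=1e-12
        )

    def test_saturated_universe(self):
        assert hypergeom_p(3, 5, 10, 10) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_non_increasing_in_x(self):
        ps = [hypergeom_p(x, 10, 20, 100) for x in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_scipy_on_larger_parameters(self):
        for x, k, m, n in [(3, 20, 50, 1000), (12, 40, 60, 500), (1, 5, 5, 30)]:
            assert hypergeom_p(x, k, m, n) == pytest.approx(
                float(stats.hypergeom.sf(x - 1, n, m, k)), rel=1e-10
            )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 5, 11, 10)


class TestEnrich:
    @pytest.fixture
    def planted(self):
        cfg = SynthConfig(n_genes=400, seed=25)
        sensitive = [f"gene{i:05d}" for i in range(60)]
        dag, direct = generate_ontology(
            60, 400, cfg, planted={"GO:0900000": sensitive}
        )
        return dag, propagate(dag, direct), sensitive

    def test_selecting_entire_universe_saturates(self, planted):
        dag, ann, _ = planted
        table = enrich_genes(ann.universe, ann, dag)
        assert (table["x"] == table["m"]).all()
        np.testing.assert_allclose(table["p_raw"], 1.0)

    def test_planted_term_ranks_first(self, planted):
        dag, ann, sensitive = planted
        table = enrich_genes(set(sensitive), ann, dag)
        assert table.iloc[0]["term"] == "GO:0900000"
        assert table.iloc[0]["p_adjusted"] < math.exp(-3)

    def test_k_and_n_constant_across_terms(self, planted):
        dag, ann, sensitive = planted
        table = enrich_genes(set(sensitive[:20]), ann, dag)
        assert table["n"].nunique() == 1
        assert table["k"].nunique() == 1
        assert table["n"].iloc[0] == len(ann.universe)

    def test_empty_selection_warns_and_returns_empty(self, planted):
        dag, ann, _ = planted
        with pytest.warns(UserWarning):
            table = enrich_genes(set(), ann, dag)
        assert table.empty

    def test_genes_outside_universe_dropped_with_warning(self, planted):
        dag, ann, sensitive = planted
        with pytest.warns(UserWarning):
            a = enrich_genes(set(sensitive) | {"NOT_A_GENE"}, ann, dag)
        b = enrich_genes(set(sensitive), ann, dag)
        pd.testing.assert_frame_equal(a, b)

    def test_bonferroni_option(self, planted):
        dag, ann, sensitive = planted
        bh = enrich_genes(set(sensitive), ann, dag, adjust="bh")
        bf = enrich_genes(set(sensitive), ann, dag, adjust="bonferroni")
        merged = bh.merge(bf, on="term", suffixes=("_bh", "_bf"))
        assert (merged["p_adjusted_bf"] >= merged["p_adjusted_bh"] - 1e-12).all()
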