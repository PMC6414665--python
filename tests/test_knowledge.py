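"""Prior-knowledge features against exhaustive brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from mfr import (
    AnnotationMap,
    GoSimilarity,
    HomologyProfileSet,
    Ontology,
    go_similarity,
    homology_similarity,
    localization_similarity,
    reactome_similarity,
    regulatory_similarity,
    term_probability,
)
from mfr.errors import MissingFeatureError
from mfr.synthetic import make_toy_ontology


# ---------------------------------------------------------------------------
# Independent oracles (edge-list traversal, no Ontology helpers)
# ---------------------------------------------------------------------------

def descendants_oracle(edges, term):
    """All terms from which ``term`` is reachable along child->parent edges."""
    children = {}
    for c, p in edges:
        children.setdefault(p, set()).add(c)
    out, stack = set(), [term]
    while stack:
        for c in children.get(stack.pop(), ()):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def ancestors_oracle(edges, term):
    parents = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    out, stack = {term}, [term]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def go_sim_oracle(ontology, ann_i, ann_j):
    """Triple loop over (o, q, common ancestor) with explicit probabilities."""
    edges = ontology.is_a_edges
    all_terms = ontology.terms
    d_root = len(descendants_oracle(edges, ontology.root))
    prob = {t: (len(descendants_oracle(edges, t)) + 1) / (d_root + 1) for t in all_terms}
    best = 0.0
    for o in ann_i:
        for q in ann_j:
            common = ancestors_oracle(edges, o) & ancestors_oracle(edges, q)
            pms = min(prob[c] for c in common)
            if pms >= 1.0:
                continue
            best = max(best, 2 * math.log(pms) / (math.log(prob[o]) + math.log(prob[q])))
    return best


def random_dag_ontology(rng, n_terms=12):
    """Random rooted DAG: each non-root term gets 1-2 parents among earlier terms."""
    terms = [f"X{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_par = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[int(p)]))
    return Ontology(set(terms), edges, terms[0])


# ---------------------------------------------------------------------------
# Term probability
# ---------------------------------------------------------------------------

class TestTermProbability:
    def test_root_probability_one(self):
        onto, _ = make_toy_ontology(depth=2, branching=2, seed=0)
        assert term_probability(onto)[onto.root] == 1.0

    def test_leaf_probability(self):
        onto, levels = make_toy_ontology(depth=2, branching=2, seed=0)
        p = term_probability(onto)
        leaf = next(t for t, l in levels.items() if l == 2)
        assert p[leaf] == pytest.approx(1 / 7)  # |D(root)| = 6

    def test_binary_tree_internal_node(self):
        # 7-term binary tree: internal node has 2 descendants, root has 6
        onto, levels = make_toy_ontology(depth=2, branching=2, seed=0)
        p = term_probability(onto)
        internal = next(t for t, l in levels.items() if l == 1)
        assert p[internal] == pytest.approx(3 / 7)

    def test_monotone_along_dag(self, rng):
        for _ in range(10):
            onto = random_dag_ontology(rng)
            p = term_probability(onto)
            for child, parent in onto.is_a_edges:
                assert p[parent] >= p[child]

    def test_matches_descendant_enumeration_oracle(self, rng):
        for _ in range(20):
            onto = random_dag_ontology(rng)
            p = term_probability(onto)
            d_root = len(descendants_oracle(onto.is_a_edges, onto.root))
            for t in onto.terms:
                expected = (len(descendants_oracle(onto.is_a_edges, t)) + 1) / (d_root + 1)
                assert p[t] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# GO similarity
# ---------------------------------------------------------------------------

class TestGoSimilarity:
    def test_shared_non_root_term_gives_one(self):
        onto, levels = make_toy_ontology(depth=2, branching=2, seed=0)
        leaf = next(t for t, l in levels.items() if l == 2)
        ann = AnnotationMap({"g1": {leaf}, "g2": {leaf}})
        assert go_similarity(onto, ann, "g1", "g2") == pytest.approx(1.0)

    def test_root_only_common_ancestor_gives_zero(self):
        onto, levels = make_toy_ontology(depth=2, branching=2, seed=0)
        internals = sorted(t for t, l in levels.items() if l == 1)
        ann = AnnotationMap({"g1": {internals[0]}, "g2": {internals[1]}})
        assert go_similarity(onto, ann, "g1", "g2") == 0.0

    def test_self_similarity_and_symmetry(self, rng):
        onto = random_dag_ontology(rng)
        non_root = sorted(onto.terms - {onto.root})
        ann = AnnotationMap({"a": {non_root[0], non_root[3]}, "b": {non_root[1]}})
        sim = GoSimilarity(onto, ann)
        assert sim("a", "a") == pytest.approx(1.0)
        assert sim("a", "b") == pytest.approx(sim("b", "a"))

    def test_unannotated_gene_missing(self):
        onto, _ = make_toy_ontology(depth=2, branching=2, seed=0)
        ann = AnnotationMap({"g1": {onto.root}})
        with pytest.raises(MissingFeatureError):
            go_similarity(onto, ann, "g1", "g2")

    def test_matches_exhaustive_oracle_on_random_dags(self, rng):
        checked = 0
        for _ in range(100):
            onto = random_dag_ontology(rng, n_terms=14)
            terms = sorted(onto.terms - {onto.root})
            oi = set(rng.choice(terms, size=3, replace=False))
            oj = set(rng.choice(terms, size=3, replace=False))
            ann = AnnotationMap({"gi": oi, "gj": oj})
            got = go_similarity(onto, ann, "gi", "gj")
            expected = go_sim_oracle(onto, oi, oj)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)
            checked += 1
        assert checked == 100


# ---------------------------------------------------------------------------
# Localization similarity
# ---------------------------------------------------------------------------

class TestLocalizationSimilarity:
    @pytest.mark.parametrize(
        "li, lj, expected",
        [({"a", "b"}, {"a", "b"}, 1.0), ({"a"}, {"b"}, 0.0), ({"a", "b"}, {"b", "c"}, 1 / 3)],
    )
    def test_jaccard_cases(self, li, lj, expected):
        ann = AnnotationMap({"g1": li, "g2": lj}, "cellular_component")
        assert localization_similarity(ann, "g1", "g2") == pytest.approx(expected)

    def test_unlocalized_gene_missing(self):
        ann = AnnotationMap({"g1": {"a"}}, "cellular_component")
        with pytest.raises(MissingFeatureError):
            localization_similarity(ann, "g1", "g2")


# ---------------------------------------------------------------------------
# Homology similarity
# ---------------------------------------------------------------------------

class TestHomologySimilarity:
    def test_identical_profiles_give_one(self):
        v = np.array([1, 0, 1, 1, 0])
        hp = HomologyProfileSet({"a": v, "b": v.copy()}, 5)
        assert homology_similarity(hp, "a", "b") == pytest.approx(1.0)

    def test_disjoint_profiles_published_panel_size(self):
        # N=21 species, n_i=n_j=10, M=0 -> -100/110 = -10/11
        vi = np.array([1] * 10 + [0] * 11)
        vj = np.array([0] * 11 + [1] * 10)
        hp = HomologyProfileSet({"a": vi, "b": vj}, 21)
        assert homology_similarity(hp, "a", "b") == pytest.approx(-10 / 11)

    def test_equals_pearson_of_binary_profiles(self, rng):
        hp_n = 21
        for _ in range(200):
            vi = rng.integers(0, 2, size=hp_n)
            vj = rng.integers(0, 2, size=hp_n)
            if vi.sum() in (0, hp_n) or vj.sum() in (0, hp_n):
                continue
            hp = HomologyProfileSet({"a": vi, "b": vj}, hp_n)
            expected = np.corrcoef(vi, vj)[0, 1]
            assert homology_similarity(hp, "a", "b") == pytest.approx(expected, rel=1e-12)

    def test_degenerate_profile_missing(self):
        hp = HomologyProfileSet({"a": np.ones(5, dtype=int), "b": np.array([1, 0, 0, 0, 1])}, 5)
        with pytest.raises(MissingFeatureError):
            homology_similarity(hp, "a", "b")


# ---------------------------------------------------------------------------
# Pathway-graph similarity
# ---------------------------------------------------------------------------

class TestReactomeSimilarity:
    def test_path_graph_cases(self):
        g = nx.path_graph(5)  # diameter 4
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(5)})
        assert reactome_similarity(g, "g0", "g1") == pytest.approx(0.75)
        assert reactome_similarity(g, "g0", "g4") == 0.0  # realizes the diameter
        assert reactome_similarity(g, "g2", "g2") == 1.0

    def test_disconnected_pair_is_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        assert reactome_similarity(g, "a", "x") == 0.0

    def test_absent_gene_missing(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(MissingFeatureError):
            reactome_similarity(g, "a", "zzz")

    def test_matches_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(15, 0.25, seed=42)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(15)})
        dis_max = max(
            d for n in g for d in nx.single_source_shortest_path_length(g, n).values()
        )
        from mfr import ReactomeSimilarity

        rx = ReactomeSimilarity(g)
        nodes = sorted(g.nodes)
        for _ in range(100):
            a, b = (nodes[k] for k in rng.integers(0, len(nodes), size=2))
            try:
                dis = nx.shortest_path_length(g, a, b)
            except nx.NetworkXNoPath:
                dis = dis_max
            assert rx(a, b) == pytest.approx(1 - dis / dis_max, rel=1e-12)
        assert all(0 <= rx(a, b) <= 1 for a in nodes[:5] for b in nodes[:5])


# ---------------------------------------------------------------------------
# Regulatory similarity
# ---------------------------------------------------------------------------

class TestRegulatorySimilarity:
    def test_direction_agnostic(self):
        pairs = {("TF1", "tgt1")}
        assert regulatory_similarity(pairs, "tgt1", "TF1") == 1
        assert regulatory_similarity(pairs, "TF1", "tgt1") == 1
        assert regulatory_similarity(pairs, "TF1", "tgt2") == 0

    def test_indexed_lookup_vs_scan(self, rng):
        genes = [f"g{i}" for i in range(30)]
        pairs = set()
        for _ in range(60):
            a, b = (genes[k] for k in rng.integers(0, 30, size=2))
            if a != b:
                pairs.add((a, b))
        for _ in range(1000):
            a, b = (genes[k] for k in rng.integers(0, 30, size=2))
            expected = int(any(p == (a, b) or p == (b, a) for p in pairs))
            assert regulatory_similarity(pairs, a, b) == expected
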