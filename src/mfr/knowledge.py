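"""The five prior-knowledge-based gene-pair features.

goSim  — Lin-style semantic similarity over biological-process ontology
         terms: maximized over annotation term pairs of
         2*log(Pms) / (log P(o) + log P(q)), with Pms the probability of
         the most specific common ancestor and P(o) derived from
         descendant counts.
lcSim  — Jaccard index of the two genes' cellular-component sets.
hgSim  — phi-type correlation of binary presence/absence profiles across
         a species panel (phylogenetic profiling similarity).
rxSim  — 1 - dis/dis_max on a pathway-derived interaction graph, with dis
         the unweighted shortest-path distance.
trSim  — indicator that a transcriptional regulatory record exists for
         the pair (direction-agnostic).

Every feature raises :class:`~mfr.errors.MissingFeatureError` when its
inputs do not cover the pair; the model layer decides whether to drop the
pair or impute.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .errors import MissingFeatureError
from .io import AnnotationMap, HomologyProfileSet, Ontology


# ---------------------------------------------------------------------------
# Term probabilities and GO similarity
# ---------------------------------------------------------------------------

def term_probability(ontology: Ontology) -> dict[str, float]:
    """P(o) = (|D(o)| + 1) / (|D(root)| + 1) for every term.

    D(o) is the descendant set of o with o excluded, so P(root) = 1 exactly
    and leaves get probability 1/(|D(root)|+1).
    """
    # count descendants by a reverse topological sweep over child->parent DAG
    desc: dict[str, set[str]] = {t: set() for t in ontology.terms}
    for t in nx.topological_sort(ontology.graph):  # children before parents
        for p in ontology.parents(t):
            desc[p].add(t)
            desc[p] |= desc[t]
    denom = len(desc[ontology.root]) + 1
    return {t: (len(d) + 1) / denom for t, d in desc.items()}


class GoSimilarity:
    """Pairwise Lin-style similarity with cached ancestor sets and P table."""

    def __init__(self, ontology: Ontology, annotations: AnnotationMap):
        annotations.validate_against(ontology)
        self.ontology = ontology
        self.annotations = annotations
        self.prob = term_probability(ontology)
        self._anc: dict[str, set[str]] = {}

    def _ancestors(self, term: str) -> set[str]:
        if term not in self._anc:
            # a term counts as its own ancestor for the common-ancestor set
            self._anc[term] = self.ontology.ancestors(term, include_self=True)
        return self._anc[term]

    def term_pair(self, o: str, q: str) -> float:
        common = self._ancestors(o) & self._ancestors(q)
        pms = min(self.prob[c] for c in common)
        if pms >= 1.0:
            return 0.0  # only the root is shared: no information in common
        num = 2.0 * math.log(pms)
        den = math.log(self.prob[o]) + math.log(self.prob[q])
        return num / den

    def __call__(self, gene_i: str, gene_j: str) -> float:
        oi = self.annotations.terms_for(gene_i)
        oj = self.annotations.terms_for(gene_j)
        if not oi or not oj:
            raise MissingFeatureError(f"goSim undefined: ({gene_i}, {gene_j}) not both annotated")
        return max(self.term_pair(o, q) for o in oi for q in oj)


def go_similarity(
    ontology: Ontology, annotations: AnnotationMap, gene_i: str, gene_j: str
) -> float:
    """One-shot convenience wrapper over :class:`GoSimilarity`."""
    return GoSimilarity(ontology, annotations)(gene_i, gene_j)


# ---------------------------------------------------------------------------
# Localization, homology, pathway-graph, regulatory similarities
# ---------------------------------------------------------------------------

def localization_similarity(
    annotations_cc: AnnotationMap, gene_i: str, gene_j: str
) -> float:
    """Jaccard index of the two genes' cellular-component term sets."""
    li = annotations_cc.terms_for(gene_i)
    lj = annotations_cc.terms_for(gene_j)
    if not li or not lj:
        raise MissingFeatureError(f"lcSim undefined: ({gene_i}, {gene_j}) not both localized")
    return len(li & lj) / len(li | lj)


def homology_similarity(
    profiles: HomologyProfileSet, gene_i: str, gene_j: str
) -> float:
    """(N*M - n_i*n_j) / sqrt((N*n_i - n_i^2)(N*n_j - n_j^2)).

    N is the species-panel size, n_i/n_j the per-gene presence counts and M
    the joint presence count; algebraically this is the phi coefficient
    (Pearson correlation of the two 0/1 profiles). Undefined when a gene is
    absent everywhere or present everywhere (n = 0 or n = N).
    """
    pi = profiles.profile(gene_i)
    pj = profiles.profile(gene_j)
    if pi is None or pj is None:
        raise MissingFeatureError(f"hgSim undefined: ({gene_i}, {gene_j}) not both profiled")
    n = profiles.species_count
    ni, nj = int(pi.sum()), int(pj.sum())
    m = int((pi & pj).sum())
    denom_sq = (n * ni - ni * ni) * (n * nj - nj * nj)
    if denom_sq <= 0:
        raise MissingFeatureError(
            f"hgSim undefined for ({gene_i}, {gene_j}): degenerate profile (n=0 or n=N)"
        )
    return (n * m - ni * nj) / math.sqrt(denom_sq)


class ReactomeSimilarity:
    """rxSim = 1 - dis/dis_max on a pathway-derived interaction graph.

    dis is the unweighted shortest-path distance; dis_max the largest
    finite pairwise distance in the graph (computed once). Disconnected
    pairs are treated as being at dis_max, i.e. rxSim = 0.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.dis_max = self._max_finite_distance(graph)
        self._bfs_cache: dict[str, dict[str, int]] = {}

    @staticmethod
    def _max_finite_distance(graph: nx.Graph) -> int:
        best = 1
        for comp in nx.connected_components(graph):
            sub = graph.subgraph(comp)
            if len(comp) > 1:
                best = max(best, nx.diameter(sub))
        return best

    def _dist(self, gene_i: str, gene_j: str) -> int:
        if gene_i == gene_j:
            return 0
        if gene_i not in self._bfs_cache:
            self._bfs_cache[gene_i] = nx.single_source_shortest_path_length(
                self.graph, gene_i
            )
        return self._bfs_cache[gene_i].get(gene_j, self.dis_max)

    def __call__(self, gene_i: str, gene_j: str) -> float:
        if gene_i not in self.graph or gene_j not in self.graph:
            raise MissingFeatureError(
                f"rxSim undefined: ({gene_i}, {gene_j}) not both in the pathway graph"
            )
        return 1.0 - min(self._dist(gene_i, gene_j), self.dis_max) / self.dis_max


def reactome_similarity(graph: nx.Graph, gene_i: str, gene_j: str) -> float:
    """One-shot convenience wrapper over :class:`ReactomeSimilarity`."""
    return ReactomeSimilarity(graph)(gene_i, gene_j)


def regulatory_similarity(
    pairs: set[tuple[str, str]], gene_i: str, gene_j: str
) -> int:
    """1 if a regulatory record exists in either direction, else 0."""
    return int((gene_i, gene_j) in pairs or (gene_j, gene_i) in pairs)
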