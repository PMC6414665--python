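"""Shortest-path transfer of GO annotations on a relatedness network.

Relatedness scores are first rank-normalized onto a reference value
distribution (in the original protocol: the corresponding Pearson
correlation values), edges with weight below a cutoff (default 0.6) are
removed, and for every pair of annotated genes the shortest paths (edge
length 1 - weight) are enumerated. An unannotated query gene lying on such
a path receives the lowest (deepest) common ancestor of the path's
annotated genes' GO terms, subject to a depth rule relative to the
ontology root. Predictions are scored as L0 (exact annotation match) or
L1 (direct parent of a known annotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import SizeError, ValidationError
from .io import AnnotationMap, Ontology


# ---------------------------------------------------------------------------
# Rank normalization
# ---------------------------------------------------------------------------

def rank_normalize_to_reference(values, reference_values) -> np.ndarray:
    """Replace each value by the reference value of the same rank.

    Both vectors are aligned descending: the largest value maps to the
    largest reference value, and so on. Tied values all receive the mean
    of the reference values over their tied rank positions, so the output
    depends on the input only through its ranks.
    """
    v = np.asarray(values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if v.shape != ref.shape or v.ndim != 1:
        raise SizeError(f"length mismatch: {v.shape} vs {ref.shape}")
    ref_sorted = np.sort(ref)  # ascending
    order = np.argsort(v, kind="stable")
    out = np.empty_like(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        fill = ref_sorted[i: j + 1].mean()
        out[order[i: j + 1]] = fill
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_weighted_network(
    genes: list[str], relatedness: np.ndarray, cutoff: float = 0.6
) -> nx.Graph:
    """Keep edges with weight >= cutoff (strictly smaller weights removed)."""
    w = np.asarray(relatedness, dtype=float)
    if w.shape != (len(genes), len(genes)):
        raise ValidationError(f"relatedness shape {w.shape} does not match {len(genes)} genes")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if np.isfinite(w[i, j]) and w[i, j] >= cutoff:
                g.add_edge(genes[i], genes[j], weight=float(w[i, j]), length=1.0 - float(w[i, j]))
    return g


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class FunctionPrediction:
    gene: str
    terms: set[str]
    supported_by: set[str]  # annotated genes whose paths cover the query


def _lowest_common_ancestors(
    term_sets: list[set[str]], ontology: Ontology, levels: dict[str, int]
) -> set[str]:
    """Deepest terms in the intersection of the genes' ancestor closures."""
    closures = []
    for terms in term_sets:
        closure: set[str] = set()
        for t in terms:
            closure |= ontology.ancestors(t, include_self=True)
        closures.append(closure)
    common = set.intersection(*closures) if closures else set()
    if not common:
        return set()
    deepest = max(levels[t] for t in common)
    return {t for t in common if levels[t] == deepest}


def predict_functions(
    network: nx.Graph,
    annotations: AnnotationMap,
    ontology: Ontology,
    query_genes: list[str],
    depth_threshold: int = 3,
    invert_depth_rule: bool = False,
) -> list[FunctionPrediction]:
    """Assign GO terms to unannotated query genes on shortest paths.

    For every pair of annotated genes, all shortest paths under edge
    length 1 - weight are enumerated; a query gene interior to such a path
    collects the annotated genes on that path and is assigned the lowest
    common ancestor(s) of their term sets. With the literal depth rule an
    ancestor is assigned when its level (longest path from the root) is
    below ``depth_threshold``; ``invert_depth_rule`` assigns when the
    level is at least the threshold instead. Query genes off every path
    (or disconnected) get no prediction.
    """
    levels = ontology.levels()
    annotated = [
        g for g in network.nodes
        if g not in query_genes and annotations.terms_for(g)
    ]
    annotated_set = set(annotated)
    query_set = set(query_genes)
    # query gene -> annotated genes co-occurring on shortest paths through it
    support: dict[str, set[str]] = {q: set() for q in query_genes}
    for ai in range(len(annotated)):
        for bi in range(ai + 1, len(annotated)):
            a, b = annotated[ai], annotated[bi]
            try:
                paths = nx.all_shortest_paths(network, a, b, weight="length")
                for path in paths:
                    interior_queries = [g for g in path if g in query_set]
                    if not interior_queries:
                        continue
                    on_path_annotated = {g for g in path if g in annotated_set}
                    for q in interior_queries:
                        support[q] |= on_path_annotated
            except nx.NetworkXNoPath:
                continue
            except nx.NodeNotFound:
                continue
    predictions = []
    for q in query_genes:
        if not support[q]:
            continue
        term_sets = [annotations.terms_for(g) for g in support[q]]
        lcas = _lowest_common_ancestors(term_sets, ontology, levels)
        if invert_depth_rule:
            kept = {t for t in lcas if levels[t] >= depth_threshold}
        else:
            kept = {t for t in lcas if levels[t] < depth_threshold}
        if kept:
            predictions.append(FunctionPrediction(q, kept, support[q]))
    return predictions


def l0_l1_match_rates(
    predictions: list[FunctionPrediction],
    truth_annotations: AnnotationMap,
    ontology: Ontology,
    total_query_genes: int,
) -> tuple[float, float]:
    """Fractions of query genes matched exactly (L0) or at direct parents (L1).

    A gene counts toward L0 when any predicted term is among its known
    terms, and toward L1 when any predicted term is a direct parent of a
    known term; the two counts are independent and each is divided by the
    total number of query genes.
    """
    if total_query_genes <= 0:
        return 0.0, 0.0
    l0 = l1 = 0
    for pred in predictions:
        known = truth_annotations.terms_for(pred.gene) or set()
        direct_parents: set[str] = set()
        for t in known:
            direct_parents |= ontology.parents(t)
        if pred.terms & known:
            l0 += 1
        if pred.terms & direct_parents:
            l1 += 1
    return l0 / total_query_genes, l1 / total_query_genes
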