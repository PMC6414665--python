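"""Relatedness-network construction, module detection and enrichment.

The workflow mirrored here: call up-regulated genes from paired
cancer/normal expression, score relatedness between them, convert scores
to Mutual Rank (MR) values, keep edges whose MR is among each node's top
three, find modules by fast-greedy (Clauset–Newman–Moore) modularity
optimization, and test marker-containing modules for pathway enrichment
with the hypergeometric tail and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MFRError, SizeError, ValidationError
from .io import ExpressionMatrix

#: Default gene universe size for enrichment (number of human genes).
DEFAULT_GENE_UNIVERSE = 18420


# ---------------------------------------------------------------------------
# Mutual rank
# ---------------------------------------------------------------------------

def mutual_rank(relatedness: np.ndarray) -> np.ndarray:
    """MR(i,j) = sqrt(rank_i(j) * rank_j(i)) from a gene x gene score matrix.

    rank_i(j) is j's 1-based position in gene i's score list sorted
    descending with the gene itself excluded; ties get average ranks. The
    result is symmetric even for asymmetric input; the diagonal is NaN.
    """
    s = np.asarray(relatedness, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {s.shape}")
    n = s.shape[0]
    if n < 3:
        raise SizeError(f"mutual rank needs at least 3 genes, got {n}")
    ranks = np.empty_like(s)
    for i in range(n):
        row = np.delete(s[i], i)
        r = stats.rankdata(-row, method="average")  # descending
        ranks[i, np.arange(n) != i] = r
        ranks[i, i] = np.nan
    mr = np.sqrt(ranks * ranks.T)
    return mr


def top_k_mr_graph(mr: np.ndarray, gene_ids: list[str], k: int = 3) -> nx.Graph:
    """Edge (i, j) iff j is among i's k smallest-MR partners or vice versa."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    mr = np.asarray(mr, dtype=float)
    n = mr.shape[0]
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    for i in range(n):
        row = mr[i].copy()
        row[i] = np.inf
        order = np.argsort(row, kind="stable")
        for j in order[: min(k, n - 1)]:
            if np.isfinite(row[j]):
                g.add_edge(gene_ids[i], gene_ids[int(j)], mr=float(row[j]))
    return g


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def fast_greedy_modules(graph: nx.Graph) -> list[set[str]]:
    """Clauset–Newman–Moore greedy modularity maximization.

    Returns the node partition at maximum modularity Q, largest module
    first. Isolated nodes form their own singleton modules.
    """
    if graph.number_of_nodes() == 0:
        raise MFRError("cannot detect modules in an empty graph")
    if graph.number_of_edges() == 0:
        return [{n} for n in graph.nodes]
    communities = greedy_modularity_communities(graph)
    return [set(c) for c in communities]


def partition_modularity(graph: nx.Graph, partition: list[set[str]]) -> float:
    return modularity(graph, partition)


# ---------------------------------------------------------------------------
# Up-regulation calling
# ---------------------------------------------------------------------------

@dataclass
class UpRegulatedGene:
    gene: str
    fold_change: float
    p_value: float
    q_value: float
    called: bool


def call_upregulated(
    cancer: ExpressionMatrix,
    normal: ExpressionMatrix,
    fold_change_cutoff: float = 1.5,
    q_cutoff: float = 0.05,
    fold_change_scale: str = "linear",
) -> list[UpRegulatedGene]:
    """Call genes up-regulated in cancer vs normal samples.

    A gene is called when its fold change exceeds ``fold_change_cutoff``
    and its BH-adjusted Welch t-test q-value (t-test on the log2 values)
    is below ``q_cutoff``. With ``fold_change_scale="linear"`` the fold
    change is the ratio of linear-scale means (2**x un-logged); with
    "log2" it is 2**(difference of log2 means).
    """
    common = [g for g in cancer.gene_ids if g in normal]
    if not common:
        raise ValidationError("cancer and normal matrices share no genes")
    if cancer.n_samples < 3 or normal.n_samples < 3:
        raise SizeError("need at least 3 samples per group")
    if fold_change_scale not in ("linear", "log2"):
        raise ValidationError(f"unknown fold_change_scale {fold_change_scale!r}")
    pvals, fcs = [], []
    for g in common:
        xc, xn = cancer.row(g), normal.row(g)
        if fold_change_scale == "linear":
            fc = float(np.mean(2.0 ** xc) / np.mean(2.0 ** xn))
        else:
            fc = float(2.0 ** (np.mean(xc) - np.mean(xn)))
        t = stats.ttest_ind(xc, xn, equal_var=False)
        pvals.append(float(t.pvalue))
        fcs.append(fc)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for g, fc, p, q in zip(common, fcs, pvals, qvals):
        called = fc > fold_change_cutoff and q < q_cutoff
        out.append(UpRegulatedGene(g, fc, p, float(q), called))
    return out


# ---------------------------------------------------------------------------
# Pathway enrichment (hypergeometric tail + BH)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    pathway: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float = float("nan")

    @property
    def enriched(self) -> bool:
        return self.q_value < 0.01


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): 1 - sum_{i<k} pmf(i)."""
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K={K}, n={n})")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    gene_set: set[str],
    pathway_map: dict[str, set[str]],
    N: int = DEFAULT_GENE_UNIVERSE,
    q_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``gene_set`` in each pathway.

    q-values are BH-adjusted across the tested pathways; a pathway is
    flagged enriched at q < ``q_cutoff`` (default 0.01).
    """
    n = len(gene_set)
    results = []
    for pathway, members in sorted(pathway_map.items()):
        K = len(members)
        k = len(gene_set & members)
        p = hypergeom_pvalue(k, K, n, N)
        results.append(EnrichmentResult(pathway, k, K, n, N, p))
    if results:
        _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return results


# ---------------------------------------------------------------------------
# Marker genes and the end-to-end cancer-network pipeline
# ---------------------------------------------------------------------------

def load_marker_genes() -> list[str]:
    """The packaged 21 glutamine/glutamate-metabolism marker genes."""
    text = (
        importlib.resources.files("mfr.data").joinpath("glutamine_markers.tsv").read_text()
    )
    genes = []
    for i, line in enumerate(text.splitlines()):
        if i == 0 or not line.strip():
            continue
        genes.append(line.split("\t")[0])
    return genes


@dataclass
class CancerNetworkResult:
    upregulated: list[str]
    graph: nx.Graph
    modules: list[set[str]]
    marker_modules: list[set[str]]
    enrichment: dict[int, list[EnrichmentResult]]


def cancer_network_pipeline(
    cancer: ExpressionMatrix,
    normal: ExpressionMatrix,
    relatedness_fn,
    pathway_map: dict[str, set[str]],
    markers: list[str] | None = None,
    N: int = DEFAULT_GENE_UNIVERSE,
    k: int = 3,
) -> CancerNetworkResult:
    """Up-regulation calling -> relatedness -> MR top-k graph -> modules ->
    enrichment of marker-containing modules.

    ``relatedness_fn(gene_a, gene_b) -> float`` supplies pairwise scores
    (typically an MFR model over assembled features).
    """
    markers = markers if markers is not None else load_marker_genes()
    calls = call_upregulated(cancer, normal)
    up = [c.gene for c in calls if c.called]
    if len(up) < 3:
        raise SizeError(f"only {len(up)} up-regulated genes; need >= 3 for MR")
    scores = np.zeros((len(up), len(up)))
    for i, a in enumerate(up):
        for j in range(i + 1, len(up)):
            s = float(relatedness_fn(a, up[j]))
            scores[i, j] = scores[j, i] = s
    mr = mutual_rank(scores)
    graph = top_k_mr_graph(mr, up, k=k)
    modules = fast_greedy_modules(graph)
    marker_set = set(markers)
    marker_modules = [m for m in modules if m & marker_set]
    enrichment = {
        i: enrich_pathways(mod, pathway_map, N=N)
        for i, mod in enumerate(modules)
        if mod in marker_modules
    }
    return CancerNetworkResult(up, graph, modules, marker_modules, enrichment)
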