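"""Seeded generators for every input resource, with planted structure.

The generators emulate the study's data sources at desk scale: a
gene x sample expression matrix with coexpressed gene modules driven by
shared latent factors, a toy rooted ontology, annotation maps whose
in-module genes share a term block, correlated binary homology profiles
over a species panel, a pathway-interaction graph with module cliques,
and a regulator->target pair list. Modules come in three kinds —
"both" (coexpressed and annotation-coherent), "expr_only" (coexpressed
but incoherent) and "knowledge_only" (coherent but not coexpressed) —
so labeled pair datasets can plant exactly the signal each evaluation
needs. Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import MFRError, ValidationError
from .expression import ExpressionFeatureConfig
from .io import (
    AnnotationMap,
    ExpressionMatrix,
    HomologyProfileSet,
    Ontology,
    PairDataset,
    PairRecord,
)
from .model import PairFeatureResources

MODULE_KINDS = ("both", "expr_only", "knowledge_only")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic resources.

    module_coexpression is the target within-module Pearson correlation
    (latent-factor loading sqrt(rho)); annotation_coherence the
    probability that an in-module gene carries the module's term block;
    species_count the homology-panel size (21 species).
    """

    n_genes: int = 300
    n_samples: int = 100
    n_modules: int = 10
    module_coexpression: float = 0.8
    annotation_coherence: float = 0.9
    species_count: int = 21
    noise_sd: float = 1.0
    profile_flip_prob: float = 0.1
    regulatory_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.module_coexpression, self.annotation_coherence,
                  self.profile_flip_prob, self.regulatory_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for c in (self.n_genes, self.n_samples, self.n_modules, self.species_count):
            if c <= 0:
                raise ValidationError("counts must be positive")


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def make_toy_ontology(
    depth: int = 3, branching: int = 3, seed: int = 0, cross_edge_prob: float = 0.0
) -> tuple[Ontology, dict[str, int]]:
    """Complete ``branching``-ary term tree of the given depth.

    Term count is sum(branching**i for i in 0..depth). With
    ``cross_edge_prob`` > 0 extra is-a edges to same-or-higher levels turn
    the tree into a proper DAG. Returns the ontology and each term's level.
    """
    if depth < 2 or branching < 2:
        raise ValidationError("need depth >= 2 and branching >= 2")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    levels: dict[str, int] = {}
    counter = 0

    def new_term(level: int) -> str:
        nonlocal counter
        t = f"T{counter:05d}"
        counter += 1
        levels[t] = level
        return t

    root = new_term(0)
    frontier = [root]
    by_level: dict[int, list[str]] = {0: [root]}
    for lvl in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                child = new_term(lvl)
                edges.append((child, parent))
                nxt.append(child)
        by_level[lvl] = nxt
        frontier = nxt
    if cross_edge_prob > 0:
        for lvl in range(2, depth + 1):
            for term in by_level[lvl]:
                if rng.random() < cross_edge_prob:
                    extra_parent = by_level[lvl - 1][rng.integers(len(by_level[lvl - 1]))]
                    if (term, extra_parent) not in edges:
                        edges.append((term, extra_parent))
    onto = Ontology(set(levels), edges, root, namespace="biological_process")
    return onto, levels


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _module_assignment(spec: SyntheticSpec) -> tuple[list[str], dict[str, int]]:
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    labels = {g: i % spec.n_modules for i, g in enumerate(genes)}
    return genes, labels


def make_expression(
    spec: SyntheticSpec, module_rhos: dict[int, float] | None = None
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Latent-factor expression matrix: x_g = sqrt(rho) f_m + sqrt(1-rho) eps.

    Within a module the expected pairwise Pearson correlation is rho
    (``module_rhos[m]``, default the spec's module_coexpression); between
    modules it is 0. Values are shifted to a log2-intensity-like baseline
    (gene means around 8) and flagged normalized.
    """
    rng = np.random.default_rng(spec.seed)
    genes, labels = _module_assignment(spec)
    factors = rng.standard_normal((spec.n_modules, spec.n_samples))
    values = np.empty((spec.n_genes, spec.n_samples))
    baselines = rng.uniform(6.0, 10.0, size=spec.n_genes)
    for i, g in enumerate(genes):
        m = labels[g]
        rho = spec.module_coexpression if module_rhos is None else module_rhos[m]
        eps = rng.standard_normal(spec.n_samples)
        signal = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * eps
        values[i] = baselines[i] + spec.noise_sd * signal
    matrix = ExpressionMatrix(genes, [f"S{j:03d}" for j in range(spec.n_samples)],
                              values, normalized=True)
    return matrix, labels


# ---------------------------------------------------------------------------
# Knowledge resources
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeResources:
    ontology: Ontology
    bp_annotations: AnnotationMap
    cc_annotations: AnnotationMap
    homology: HomologyProfileSet
    pathway_graph: nx.Graph
    regulatory_pairs: set[tuple[str, str]]
    module_blocks: dict[int, list[str]] = field(default_factory=dict)


def make_knowledge_resources(
    spec: SyntheticSpec,
    ontology: Ontology,
    module_labels: dict[str, int],
    module_coherences: dict[int, float] | None = None,
) -> KnowledgeResources:
    """Annotations, homology profiles, pathway graph and regulatory pairs.

    With coherence c for a module: each in-module gene carries the
    module's ontology term block with probability c (otherwise random leaf
    terms), shares the module organelle label, has a homology profile that
    is the module's species pattern with bits flipped at
    ``profile_flip_prob``, and joins the module's pathway clique. A
    ``regulatory_fraction`` of in-module ordered pairs of coherent modules
    become regulatory records.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(module_labels, key=lambda g: (module_labels[g], g))
    modules: dict[int, list[str]] = {}
    for g in genes:
        modules.setdefault(module_labels[g], []).append(g)

    levels = ontology.levels()
    max_level = max(levels.values())
    pre_leaves = sorted(t for t, l in levels.items() if l == max_level - 1)
    leaves = sorted(t for t, l in levels.items() if l == max_level)
    if len(pre_leaves) < spec.n_modules:
        raise MFRError(
            f"ontology has {len(pre_leaves)} pre-leaf terms for {spec.n_modules} modules; "
            "increase depth/branching"
        )
    block_parents = {m: pre_leaves[m] for m in modules}
    child_map: dict[str, list[str]] = {}
    for t in pre_leaves:
        child_map[t] = sorted(ontology.children(t))
    module_blocks = {m: child_map[block_parents[m]] for m in modules}

    organelles = [f"CC{m:03d}" for m in range(spec.n_modules)]
    extra_organelles = [f"CCX{i:02d}" for i in range(4)]

    bp: dict[str, set[str]] = {}
    cc: dict[str, set[str]] = {}
    profiles: dict[str, np.ndarray] = {}
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    regulatory: set[tuple[str, str]] = set()

    module_patterns = {}
    for m in modules:
        pattern = rng.integers(0, 2, size=spec.species_count)
        # keep patterns informative: at least 5 present and 5 absent species
        while pattern.sum() < 5 or pattern.sum() > spec.species_count - 5:
            pattern = rng.integers(0, 2, size=spec.species_count)
        module_patterns[m] = pattern

    for m, members in modules.items():
        coherence = (
            spec.annotation_coherence if module_coherences is None else module_coherences[m]
        )
        coherent_members = []
        for g in members:
            is_coherent = rng.random() < coherence
            if is_coherent:
                coherent_members.append(g)
                bp[g] = set(module_blocks[m])
                cc[g] = {organelles[m]}
                profile = module_patterns[m].copy()
                flips = rng.random(spec.species_count) < spec.profile_flip_prob
                profile[flips] = 1 - profile[flips]
            else:
                k = int(rng.integers(1, 4))
                bp[g] = set(rng.choice(leaves, size=k, replace=False))
                cc[g] = {extra_organelles[rng.integers(len(extra_organelles))]}
                profile = rng.integers(0, 2, size=spec.species_count)
            # avoid degenerate all-0/all-1 profiles (hgSim undefined there)
            if profile.sum() == 0:
                profile[rng.integers(spec.species_count)] = 1
            elif profile.sum() == spec.species_count:
                profile[rng.integers(spec.species_count)] = 0
            profiles[g] = profile
        # pathway clique over the coherent members
        for i in range(len(coherent_members)):
            for j in range(i + 1, len(coherent_members)):
                graph.add_edge(coherent_members[i], coherent_members[j])
        # regulatory records among coherent in-module ordered pairs
        for i in range(len(coherent_members)):
            for j in range(len(coherent_members)):
                if i != j and rng.random() < spec.regulatory_fraction:
                    regulatory.add((coherent_members[i], coherent_members[j]))

    # ring of bridges keeps the pathway graph connected across modules
    module_ids = sorted(modules)
    for a, b in zip(module_ids, module_ids[1:] + module_ids[:1]):
        graph.add_edge(modules[a][0], modules[b][0])

    return KnowledgeResources(
        ontology=ontology,
        bp_annotations=AnnotationMap(bp, "biological_process"),
        cc_annotations=AnnotationMap(cc, "cellular_component"),
        homology=HomologyProfileSet(profiles, spec.species_count),
        pathway_graph=graph,
        regulatory_pairs=regulatory,
        module_blocks=module_blocks,
    )


# ---------------------------------------------------------------------------
# Full resource bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticResources:
    spec: SyntheticSpec
    expression: ExpressionMatrix
    knowledge: KnowledgeResources
    module_labels: dict[str, int]
    module_kinds: dict[int, str]

    def modules_of_kind(self, kind: str) -> list[int]:
        return [m for m, k in self.module_kinds.items() if k == kind]

    def module_members(self, m: int) -> list[str]:
        return sorted(g for g, lab in self.module_labels.items() if lab == m)

    def pair_resources(
        self, config: ExpressionFeatureConfig | None = None
    ) -> PairFeatureResources:
        return PairFeatureResources(
            expression=self.expression,
            ontology=self.knowledge.ontology,
            bp_annotations=self.knowledge.bp_annotations,
            cc_annotations=self.knowledge.cc_annotations,
            homology=self.knowledge.homology,
            pathway_graph=self.knowledge.pathway_graph,
            regulatory_pairs=self.knowledge.regulatory_pairs,
            config=config or ExpressionFeatureConfig(),
        )


def make_resources(
    spec: SyntheticSpec,
    module_kinds: dict[int, str] | None = None,
    ontology: Ontology | None = None,
) -> SyntheticResources:
    """Generate the complete resource bundle for a spec.

    ``module_kinds`` maps module index -> "both" | "expr_only" |
    "knowledge_only"; default: all modules "both". Coexpression is planted
    for "both"/"expr_only" modules, annotation coherence for
    "both"/"knowledge_only" ones.
    """
    kinds = module_kinds or {m: "both" for m in range(spec.n_modules)}
    for m, k in kinds.items():
        if k not in MODULE_KINDS:
            raise ValidationError(f"unknown module kind {k!r} for module {m}")
    rhos = {
        m: (spec.module_coexpression if kinds.get(m, "both") in ("both", "expr_only") else 0.0)
        for m in range(spec.n_modules)
    }
    coherences = {
        m: (spec.annotation_coherence if kinds.get(m, "both") in ("both", "knowledge_only") else 0.0)
        for m in range(spec.n_modules)
    }
    expression, labels = make_expression(spec, module_rhos=rhos)
    if ontology is None:
        branching = 3
        while branching ** 2 < spec.n_modules:
            branching += 1
        ontology, _ = make_toy_ontology(depth=3, branching=branching, seed=spec.seed + 2)
    knowledge = make_knowledge_resources(spec, ontology, labels, module_coherences=coherences)
    return SyntheticResources(spec, expression, knowledge, labels, kinds)


# ---------------------------------------------------------------------------
# Labeled pairs
# ---------------------------------------------------------------------------

def make_labeled_pairs(
    resources: SyntheticResources,
    n_pos: int,
    n_neg: int,
    regime: str = "both_high",
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Sample labeled gene pairs with the planted signal of ``regime``.

    Positives are within-module pairs drawn from modules of the matching
    kind ("both_high" -> "both" modules, etc.); negatives pair genes from
    different modules by random permutation, never colliding with any
    within-module pair. Returns (gene_a, gene_b, label) triples.
    """
    regime_to_kinds = {
        "both_high": ("both",),
        "expr_only": ("expr_only",),
        "knowledge_only": ("knowledge_only",),
        "mixture": ("both", "knowledge_only"),  # half the positives from each
    }
    if regime not in regime_to_kinds:
        raise ValidationError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    positives: list[tuple[str, str]] = []
    kinds = regime_to_kinds[regime]
    quota = [n_pos // len(kinds)] * len(kinds)
    quota[0] += n_pos - sum(quota)
    for kind, n_k in zip(kinds, quota):
        eligible = resources.modules_of_kind(kind)
        if not eligible:
            raise MFRError(f"no modules of kind {kind!r} in resources")
        candidates: list[tuple[str, str]] = []
        for m in eligible:
            members = resources.module_members(m)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    candidates.append((members[i], members[j]))
        if len(candidates) < n_k:
            raise MFRError(
                f"only {len(candidates)} within-module pairs available for {n_k} "
                f"positives of kind {kind!r}"
            )
        idx = rng.choice(len(candidates), size=n_k, replace=False)
        positives.extend(candidates[i] for i in sorted(idx))
    labels = resources.module_labels
    genes = sorted(labels)
    taken = set(positives)
    negatives: list[tuple[str, str]] = []
    max_tries = 200 * max(1, n_neg)
    tries = 0
    while len(negatives) < n_neg and tries < max_tries:
        tries += 1
        a, b = (genes[k] for k in rng.integers(0, len(genes), size=2))
        if a == b or labels[a] == labels[b]:
            continue  # cross-module only: negatives carry no planted signal
        pair = (a, b) if a <= b else (b, a)
        if pair in taken:
            continue
        taken.add(pair)
        negatives.append(pair)
    if len(negatives) < n_neg:
        raise MFRError(f"could not sample {n_neg} negatives (got {len(negatives)})")
    return (
        [(a, b, 1) for a, b in positives] + [(a, b, 0) for a, b in negatives]
    )


def make_pair_dataset(
    resources: SyntheticResources, n_pos: int, n_neg: int, regime: str = "both_high",
    seed: int = 0,
) -> PairDataset:
    """Labeled pairs as a PairDataset (features not yet assembled)."""
    triples = make_labeled_pairs(resources, n_pos, n_neg, regime, seed)
    return PairDataset([PairRecord(a, b, lab, provenance=regime) for a, b, lab in triples])
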