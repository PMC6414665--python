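"""Readers/writers for the tabular and ontology inputs, plus model serialization.

The interchange dialect for every tabular resource is TSV (tab-separated,
header row, UTF-8): expression matrices (first column gene ids, header row
sample ids), gene-pair tables (geneA, geneB, label and optionally the 12
feature columns), two-column annotation tables (gene, term), homology
profiles (gene followed by one 0/1 column per species), edge lists.
Ontologies come either as a simplified OBO file (``[Term]`` stanzas with
``id:`` and ``is_a:`` lines; all other relationship types are dropped) or as
a two-column child/parent TSV. Models are serialized as JSON with a schema
version; floats survive the round-trip bit-exactly via Python's shortest
repr.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Canonical order of the 12 gene-pair features.
FEATURE_NAMES = (
    "exp1", "exp2", "PCC", "SRC", "MI", "PPC", "CMI",
    "goSim", "lcSim", "hgSim", "rxSim", "trSim",
)

EXPRESSION_FEATURES = FEATURE_NAMES[:7]
KNOWLEDGE_FEATURES = FEATURE_NAMES[7:]
COEXPRESSION_FEATURES = ("PCC", "SRC", "MI", "PPC", "CMI")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued matrix with a normalization flag.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``; after preprocessing the units are log2 intensities.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene id(s): {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample id(s): {sorted(dupes)}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def row(self, gene: str) -> np.ndarray:
        from .errors import LookupError_

        if gene not in self._index:
            raise LookupError_(f"gene {gene!r} not in expression matrix")
        return self.values[self._index[gene]]


@dataclass
class Ontology:
    """Rooted DAG of terms connected by "is a" (child -> parent) edges."""

    terms: set[str]
    is_a_edges: list[tuple[str, str]]
    root: str
    namespace: str = ""

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.is_a_edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValidationError(f"'is a' relation contains a cycle: {cyc}")
        for t in self.terms:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise ValidationError(f"term {t!r} has no path to root {self.root!r}")
        self.graph = g

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """Terms reachable by following child->parent edges (optionally + self)."""
        anc = nx.descendants(self.graph, term)
        if include_self:
            anc = anc | {term}
        return anc

    def descendants(self, term: str) -> set[str]:
        """Terms below ``term``; the term is excluded from its own descendant set."""
        return nx.ancestors(self.graph, term)

    def levels(self) -> dict[str, int]:
        """Level of each term = length of its longest path up to the root."""
        out: dict[str, int] = {self.root: 0}
        for t in reversed(list(nx.topological_sort(self.graph))):
            if t == self.root:
                continue
            parents = self.parents(t)
            out[t] = 1 + max(out[p] for p in parents)
        return out


@dataclass
class AnnotationMap:
    """Gene -> set of ontology terms, within one namespace."""

    annotations: dict[str, set[str]]
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        for g, terms in self.annotations.items():
            if not terms:
                raise ValidationError(f"gene {g!r} has an empty annotation set")

    def terms_for(self, gene: str) -> set[str] | None:
        """Annotation set, or None for a gene missing from this source."""
        return self.annotations.get(gene)

    def validate_against(self, ontology: Ontology) -> None:
        unknown = {t for s in self.annotations.values() for t in s} - ontology.terms
        if unknown:
            raise ValidationError(f"annotation terms absent from ontology: {sorted(unknown)[:5]}")


@dataclass
class HomologyProfileSet:
    """Gene -> binary presence/absence profile across a species panel."""

    profiles: dict[str, np.ndarray]
    species_count: int

    def __post_init__(self) -> None:
        for g, v in self.profiles.items():
            v = np.asarray(v, dtype=int)
            if v.shape != (self.species_count,):
                raise ValidationError(
                    f"profile for {g!r} has length {v.shape}, expected {self.species_count}"
                )
            if not np.isin(v, (0, 1)).all():
                raise ValidationError(f"profile for {g!r} has entries outside {{0,1}}")
            self.profiles[g] = v

    def profile(self, gene: str) -> np.ndarray | None:
        return self.profiles.get(gene)


@dataclass
class PairRecord:
    gene_a: str
    gene_b: str
    label: int
    features: dict[str, float] | None = None
    provenance: str = ""


@dataclass
class PairDataset:
    """Labeled, canonicalized (lexicographically ordered) gene pairs."""

    records: list[PairRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        canon: list[PairRecord] = []
        for r in self.records:
            a, b = sorted((r.gene_a, r.gene_b))
            if (a, b) in seen:
                raise ValidationError(f"duplicate gene pair after canonicalization: ({a}, {b})")
            seen.add((a, b))
            if r.label not in (0, 1):
                raise ValidationError(f"label {r.label!r} for pair ({a}, {b}) is not in {{0,1}}")
            canon.append(PairRecord(a, b, int(r.label), r.features, r.provenance))
        self.records = canon

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def feature_matrix(self) -> np.ndarray:
        """(n_pairs, 12) array in canonical feature order; missing -> NaN."""
        out = np.full((len(self.records), len(FEATURE_NAMES)), np.nan)
        for i, r in enumerate(self.records):
            if r.features is None:
                continue
            for j, name in enumerate(FEATURE_NAMES):
                if name in r.features and r.features[name] is not None:
                    out[i, j] = r.features[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"geneA": r.gene_a, "geneB": r.gene_b, "label": r.label}
            if r.features is not None:
                for name in FEATURE_NAMES:
                    row[name] = r.features.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with sample ids in the header and gene ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {raw!r} at gene {genes[i]!r} (row {i + 2}), "
                    f"sample {samples[j]!r} (column {j + 2})"
                ) from None
    return ExpressionMatrix(genes, samples, values, normalized=False)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_ontology(path, root: str | None = None, namespace: str = "") -> Ontology:
    """Read a simplified OBO file or a two-column child/parent TSV.

    Only "is a" edges are retained; other relationship types (``part_of``,
    ``regulates``...) are silently dropped. The root is inferred as the
    unique parentless term unless given explicitly.
    """
    path = str(path)
    text = open(path, encoding="utf-8").read()
    if "[Term]" in text:
        terms, edges = _parse_obo(text)
    else:
        terms, edges = _parse_edge_tsv(text)
    return _build_ontology(terms, edges, root, namespace)


def _parse_obo(text: str) -> tuple[set[str], list[tuple[str, str]]]:
    import io as _io
    import logging

    import obonet

    logging.disable(logging.WARNING)  # tolerate header-less OBO subsets
    try:
        g = obonet.read_obo(_io.StringIO(text))
    finally:
        logging.disable(logging.NOTSET)
    # keep only "is a" edges; part_of / regulates etc. intentionally dropped
    edges = [(c, p) for c, p, key in g.edges(keys=True) if key == "is_a"]
    return set(g.nodes), edges


def _parse_edge_tsv(text: str) -> tuple[set[str], list[tuple[str, str]]]:
    terms: set[str] = set()
    edges: list[tuple[str, str]] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for i, line in enumerate(lines):
        parts = line.rstrip("\n").split("\t")
        if i == 0 and parts[0].lower() in ("child", "term", "id"):
            continue
        if len(parts) < 2:
            raise ParseError(f"ontology TSV line {i + 1}: expected 2 columns, got {len(parts)}")
        child, parent = parts[0].strip(), parts[1].strip()
        relation = parts[2].strip() if len(parts) > 2 else "is_a"
        terms.update((child, parent))
        if relation in ("is_a", "is a"):
            edges.append((child, parent))
    return terms, edges


def _build_ontology(terms, edges, root, namespace) -> Ontology:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise ValidationError(f"'is a' relation contains a cycle: {cyc}")
    parentless = [t for t in terms if g.out_degree(t) == 0]
    if root is None:
        if len(parentless) != 1:
            raise ValidationError(
                f"cannot infer root: {len(parentless)} parentless terms "
                f"({sorted(parentless)[:5]}); pass root explicitly"
            )
        root = parentless[0]
    elif root not in terms:
        raise ValidationError(f"configured root {root!r} not among terms")
    # keep only terms that reach the root (others are disconnected fragments)
    reachable = nx.ancestors(g, root) | {root}
    dropped = terms - reachable
    if dropped:
        raise ValidationError(f"terms with no path to root {root!r}: {sorted(dropped)[:5]}")
    return Ontology(set(terms), [e for e in edges], root, namespace)


def read_annotations(path, namespace: str = "biological_process") -> AnnotationMap:
    """Read a GAF-like two-column TSV (gene, term)."""
    ann: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0].lower() in ("gene", "gene_id"):
                continue
            if len(parts) < 2:
                raise ParseError(f"annotation TSV line {i + 1}: expected 2 columns")
            ann.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return AnnotationMap(ann, namespace)


def write_annotations(annotations: AnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for g in sorted(annotations.annotations):
            for t in sorted(annotations.annotations[g]):
                fh.write(f"{g}\t{t}\n")


def read_homology_profiles(path) -> HomologyProfileSet:
    """Read a TSV: gene id followed by one 0/1 column per species."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = {str(g): df.loc[g].to_numpy(dtype=int) for g in df.index}
    return HomologyProfileSet(profiles, species_count=df.shape[1])


def write_homology_profiles(profiles: HomologyProfileSet, path) -> None:
    cols = [f"sp{i + 1}" for i in range(profiles.species_count)]
    df = pd.DataFrame.from_dict(
        {g: v for g, v in sorted(profiles.profiles.items())}, orient="index", columns=cols
    )
    df.to_csv(path, sep="\t", index_label="gene")


def read_interaction_graph(path, weighted: bool = False) -> nx.Graph:
    """Read a TSV edge list (geneA, geneB[, weight]) into an undirected graph."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0].lower() in ("genea", "gene_a", "source"):
                continue
            if len(parts) < 2:
                raise ParseError(f"edge list line {i + 1}: expected >=2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r} at line {i + 1}")
            if weighted and len(parts) > 2:
                w = float(parts[2])
                if not np.isfinite(w):
                    raise ValidationError(f"non-finite weight at line {i + 1}")
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
    return g


def write_interaction_graph(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("geneA\tgeneB\tweight\n")
        for a, b, data in sorted(graph.edges(data=True)):
            w = data.get("weight", "")
            fh.write(f"{a}\t{b}\t{w}\n")


def read_regulatory_pairs(path) -> set[tuple[str, str]]:
    """Read a TSV of (regulator, target) ordered pairs."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0].lower() in ("regulator", "tf"):
                continue
            if len(parts) < 2:
                raise ParseError(f"regulatory TSV line {i + 1}: expected 2 columns")
            pairs.add((parts[0].strip(), parts[1].strip()))
    return pairs


def write_regulatory_pairs(pairs: set[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_pair_dataset(path) -> PairDataset:
    """Read a TSV of (geneA, geneB, label[, 12 feature columns])."""
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str})
    required = {"geneA", "geneB", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"pair table must have columns {sorted(required)}; got {list(df.columns)}")
    has_features = all(f in df.columns for f in FEATURE_NAMES)
    records = []
    for _, row in df.iterrows():
        label = row["label"]
        if label not in (0, 1):
            raise ValidationError(f"label {label!r} for pair ({row['geneA']}, {row['geneB']})")
        feats = None
        if has_features:
            feats = {f: (float(row[f]) if pd.notna(row[f]) else np.nan) for f in FEATURE_NAMES}
        records.append(PairRecord(row["geneA"], row["geneB"], int(label), feats))
    return PairDataset(records)


def write_pair_dataset(dataset: PairDataset, path) -> None:
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Model serialization (JSON, schema-versioned)
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model, path) -> None:
    """Serialize an MFRModel to JSON; floats round-trip bit-exactly."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_names": list(FEATURE_NAMES),
        "weights": [float(w) for w in model.weights],
        "bias": float(model.bias),
        "scaler_min": None if model.scaler is None else [float(v) for v in model.scaler.min_],
        "scaler_max": None if model.scaler is None else [float(v) for v in model.scaler.max_],
        "hyperparameters": dict(model.hyperparameters),
        "metadata": dict(model.metadata),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path):
    from .model import FeatureScaler, MFRModel

    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise SchemaError(f"cannot parse model file {path}: {exc}") from None
    for key in ("schema_version", "weights", "bias", "feature_names"):
        if key not in payload:
            raise SchemaError(f"model file {path} is missing field {key!r}")
    weights = np.asarray(payload["weights"], dtype=float)
    if weights.shape != (len(FEATURE_NAMES),):
        raise SchemaError(f"model file {path}: expected {len(FEATURE_NAMES)} weights")
    scaler = None
    if payload.get("scaler_min") is not None:
        scaler = FeatureScaler(
            np.asarray(payload["scaler_min"], dtype=float),
            np.asarray(payload["scaler_max"], dtype=float),
        )
    return MFRModel(
        weights=weights,
        bias=float(payload["bias"]),
        scaler=scaler,
        hyperparameters=payload.get("hyperparameters", {}),
        metadata=payload.get("metadata", {}),
    )
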