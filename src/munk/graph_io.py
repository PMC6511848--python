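"""Readers, validators and preprocessing for networks, homolog pairs and annotations.

Protein-protein interaction (PPI) networks come in as two-column edge lists,
candidate homolog pairs as two-column TSV, ontologies as a small OBO subset and
gene annotations as three-column TSV.  All node orderings are lexicographic so
every matrix built downstream is bit-stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "HomologPairs",
    "OntologyAnnotation",
    "InputError",
    "read_edge_list",
    "largest_connected_component",
    "two_core",
    "preprocess_network",
    "read_homolog_pairs",
    "read_obo_subset",
    "read_annotations",
    "propagate_annotations",
]

#: ontology relations over which annotations are propagated to ancestors
PROPAGATED_RELATIONS = frozenset({"is_a", "part_of", "has_part"})


class InputError(ValueError):
    """Malformed or empty input data."""


@dataclass(frozen=True)
class Network:
    """An undirected, unweighted, simple graph over protein identifiers.

    Node order is always lexicographic; matrices over the network inherit it.
    """

    species_tag: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_of(self, node: str) -> int:
        return self.graph.degree[node]

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        return Network(self.species_tag, nx.Graph(self.graph.subgraph(nodes)))


@dataclass(frozen=True)
class HomologPairs:
    """An ordered one-to-one candidate set of (source_id, target_id) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class OntologyAnnotation:
    """A term DAG with typed relations plus per-species gene -> term-set maps.

    ``term_dag`` edges point child -> parent and carry a ``relation`` attribute
    (one of ``is_a``, ``part_of``, ``has_part``).
    """

    term_dag: nx.MultiDiGraph
    gene_terms: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def terms_of(self, species: str, gene: str) -> set[str]:
        return self.gene_terms.get(species, {}).get(gene, set())

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.term_dag):
            raise InputError("ontology term graph contains a cycle")
        known = set(self.term_dag.nodes)
        for species, genes in self.gene_terms.items():
            for gene, terms in genes.items():
                missing = terms - known
                if missing:
                    raise InputError(
                        f"gene {gene!r} ({species}) annotated to unknown "
                        f"terms: {sorted(missing)}"
                    )


def _iter_data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


_HEADER_TOKENS = {
    "node_a", "node_b", "source", "target", "source_id", "target_id",
    "gene_a", "gene_b", "protein_a", "protein_b", "gene", "species",
    "term", "phenotype", "phenotype_id", "gene_id", "label",
}


def _is_header(fields: list[str]) -> bool:
    return all(f.lower() in _HEADER_TOKENS for f in fields)


def read_edge_list(path, species_tag: str) -> Network:
    """Read a two-column edge list into a simple undirected :class:`Network`.

    Self loops are dropped and duplicate edges collapsed.  A third column, if
    present, is ignored with a warning (the analysis is unweighted).  An
    optional header line is recognised by its column names.
    """
    path = Path(path)
    graph = nx.Graph()
    n_lines = 0
    warned_extra = False
    for lineno, fields in _iter_data_lines(path):
        if n_lines == 0 and _is_header(fields):
            continue
        if len(fields) < 2:
            raise InputError(f"{path}:{lineno}: expected two columns, got {fields!r}")
        if len(fields) > 2 and not warned_extra:
            logger.warning(
                "%s:%d: extra columns ignored (edges treated as unweighted)",
                path, lineno,
            )
            warned_extra = True
        a, b = fields[0], fields[1]
        n_lines += 1
        if a == b:
            continue  # self loop
        graph.add_edge(a, b)
    if n_lines == 0:
        raise InputError(f"{path}: no edges found (empty or header-only file)")
    return Network(species_tag, graph)


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component; ties broken by the component
    containing the lexicographically smallest node id."""
    if net.n_nodes == 0:
        raise InputError("cannot take the largest component of an empty network")
    components = sorted(
        (sorted(c) for c in nx.connected_components(net.graph)),
        key=lambda c: (-len(c), c[0]),
    )
    return net.subgraph(components[0])


def two_core(net: Network) -> Network:
    """Iteratively peel nodes of degree < 2; the result may be empty.

    The two-core removes topologically indistinguishable leaves (two leaves on
    the same parent would otherwise receive identical diffusion scores).
    """
    return Network(net.species_tag, nx.Graph(nx.k_core(net.graph, k=2)))


def preprocess_network(net: Network) -> Network:
    """Standard preprocessing: two-core of the largest connected component."""
    return two_core(largest_connected_component(net))


def read_homolog_pairs(path, net1: Network, net2: Network) -> HomologPairs:
    """Read candidate homolog pairs, keeping only pairs whose ids are present
    in both (preprocessed) networks.  Each id is used at most once; when an id
    occurs in several pairs the first surviving occurrence wins.
    """
    path = Path(path)
    nodes1, nodes2 = set(net1.graph.nodes), set(net2.graph.nodes)
    seen_src: set[str] = set()
    seen_tgt: set[str] = set()
    pairs: list[tuple[str, str]] = []
    first = True
    for lineno, fields in _iter_data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 2:
            raise InputError(f"{path}:{lineno}: expected two columns, got {fields!r}")
        s, t = fields[0], fields[1]
        if s not in nodes1 or t not in nodes2:
            continue
        if s in seen_src or t in seen_tgt:
            continue
        seen_src.add(s)
        seen_tgt.add(t)
        pairs.append((s, t))
    if not pairs:
        raise InputError(f"{path}: no homolog pair survives network filtering")
    return HomologPairs(tuple(pairs))


def read_obo_subset(path) -> nx.MultiDiGraph:
    """Parse a minimal OBO subset: [Term] stanzas with id, is_a and
    relationship (part_of / has_part) lines.  Edges point child -> parent."""
    dag = nx.MultiDiGraph()
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id:"):
                current = line.split(":", 1)[1].strip()
                dag.add_node(current)
            elif line.startswith("is_a:") and current is not None:
                parent = line.split(":", 1)[1].strip().split("!")[0].strip()
                dag.add_edge(current, parent, relation="is_a")
            elif line.startswith("relationship:") and current is not None:
                body = line.split(":", 1)[1].strip().split("!")[0].strip()
                parts = body.split()
                if len(parts) >= 2 and parts[0] in PROPAGATED_RELATIONS:
                    dag.add_edge(current, parts[1], relation=parts[0])
    if not nx.is_directed_acyclic_graph(dag):
        raise InputError(f"{path}: ontology term graph contains a cycle")
    return dag


def read_annotations(path, term_dag: nx.MultiDiGraph) -> OntologyAnnotation:
    """Read a (gene, species, term) TSV into an :class:`OntologyAnnotation`."""
    path = Path(path)
    gene_terms: dict[str, dict[str, set[str]]] = {}
    first = True
    for lineno, fields in _iter_data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: expected three columns, got {fields!r}")
        gene, species, term = fields[0], fields[1], fields[2]
        gene_terms.setdefault(species, {}).setdefault(gene, set()).add(term)
    ann = OntologyAnnotation(term_dag, gene_terms)
    ann.validate()
    return ann


def term_ancestors(dag: nx.MultiDiGraph, term: str) -> set[str]:
    """All ancestors of ``term`` (excluding itself) along propagated relations."""
    out: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for _, parent, data in dag.out_edges(t, data=True):
            if data.get("relation") in PROPAGATED_RELATIONS and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def propagate_annotations(ann: OntologyAnnotation) -> OntologyAnnotation:
    """Close every gene's term set under ancestor traversal.

    Idempotent and monotone: term sets only grow, and a second application is a
    no-op.
    """
    ann.validate()
    # memoised ancestor closure per term
    closure: dict[str, set[str]] = {}

    def closed(term: str) -> set[str]:
        if term not in closure:
            closure[term] = {term} | term_ancestors(ann.term_dag, term)
        return closure[term]

    new_map: dict[str, dict[str, set[str]]] = {}
    for species, genes in ann.gene_terms.items():
        new_map[species] = {
            gene: set().union(*(closed(t) for t in terms)) if terms else set()
            for gene, terms in genes.items()
        }
    return OntologyAnnotation(ann.term_dag, new_map)
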