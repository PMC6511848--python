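"""Synthetic data with known ground truth.

Real cross-species analyses need PPI networks, homolog lists, annotation
corpora and phenotype-gene maps from external databases.  This module builds
small stand-ins with a planted truth so the whole pipeline can be exercised
and validated end to end:

* correlated network pairs — a duplication-divergence-style graph plus a
  partially rewired copy with a known node correspondence (the stand-in for a
  pair of species with homologs);
* degree-preserving randomizations (configuration-model stub matching) for
  the topology null;
* pathway-structured synthetic-lethal pairs — SLIs live within pathways and
  between designated redundant pathway couples;
* a toy ontology and phenotype maps correlated with the planted pathways.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import networkx as nx
import numpy as np

from .graph_io import Network, OntologyAnnotation, preprocess_network
from .pairs import canonical_pair
from .phenologs import PhenotypeGeneMap
from .sl_classify import SLDataset

__all__ = [
    "SyntheticPair",
    "make_network_pair",
    "degree_preserving_randomize",
    "plant_sl_interactions",
    "make_toy_ontology",
    "GeneratorError",
    "DEFAULT_N",
    "DEFAULT_DENSITY",
    "DEFAULT_REWIRE",
]

#: default study conditions: 300-node networks at PPI-like mean degree ~7.5,
#: 10% of target edges rewired
DEFAULT_N = 300
DEFAULT_DENSITY = 0.025
DEFAULT_REWIRE = 0.10

_MAX_ATTEMPTS = 50


class GeneratorError(RuntimeError):
    """A generator could not produce a valid fixture."""


@dataclass(frozen=True)
class SyntheticPair:
    """Two correlated networks with a known node correspondence."""

    net1: Network
    net2: Network
    truth: dict[str, str]  # net1 node -> net2 node, a bijection
    params: dict = field(default_factory=dict)

    @property
    def truth_inverse(self) -> dict[str, str]:
        return {b: a for a, b in self.truth.items()}


def _duplication_divergence_edges(
    n: int, target_m: int, rng: np.random.Generator
) -> nx.Graph:
    """Grow a graph by node duplication with partial edge retention, then
    adjust the edge count to the target by uniform additions/removals."""
    g = nx.complete_graph(4)
    p_retain, p_anchor = 0.4, 0.7
    while g.number_of_nodes() < n:
        u = int(rng.integers(g.number_of_nodes()))
        v = g.number_of_nodes()
        neighbors = list(g.neighbors(u))
        g.add_node(v)
        for w in neighbors:
            if rng.random() < p_retain:
                g.add_edge(v, w)
        if rng.random() < p_anchor or g.degree[v] == 0:
            g.add_edge(v, u)
    # top up to the requested density by triadic closure (keeps the local,
    # clustered structure of the growth process), then trim if needed
    stall = 0
    while g.number_of_edges() < target_m:
        u = int(rng.integers(n))
        nb = list(g.neighbors(u))
        if len(nb) >= 2:
            i, j = rng.choice(len(nb), size=2, replace=False)
            v, w = nb[int(i)], nb[int(j)]
            if not g.has_edge(v, w):
                g.add_edge(v, w)
                stall = 0
                continue
        stall += 1
        if stall > 50 * n:  # saturated neighborhoods: fall back to random edges
            a, b = rng.integers(n, size=2)
            if a != b and not g.has_edge(int(a), int(b)):
                g.add_edge(int(a), int(b))
    if g.number_of_edges() > target_m:
        edges = sorted(map(tuple, g.edges))
        drop = rng.choice(len(edges), size=g.number_of_edges() - target_m, replace=False)
        g.remove_edges_from(edges[i] for i in drop)
    return g


def make_network_pair(
    n: int = DEFAULT_N,
    density: float = DEFAULT_DENSITY,
    rewire_fraction: float = DEFAULT_REWIRE,
    seed: int = 0,
) -> SyntheticPair:
    """Build a correlated network pair with known correspondence.

    net1 comes from a duplication-divergence-style growth process (heavy-
    tailed degrees, like PPI networks); net2 is a relabeled copy in which
    ``rewire_fraction`` of the edges are replaced by random non-edges.
    Generation is retried (new sub-seed) until both networks survive
    two-core-of-LCC preprocessing.
    """
    if not (0 < density < 1) or not (0 <= rewire_fraction <= 1) or n < 8:
        raise GeneratorError("parameters out of range")
    target_m = round(density * n * (n - 1) / 2)
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_ATTEMPTS):
        g1 = _duplication_divergence_edges(n, target_m, rng)
        width = len(str(n - 1))
        name1 = {i: f"a{i:0{width}d}" for i in g1.nodes}
        perm = rng.permutation(n)
        name2 = {i: f"b{perm[i]:0{width}d}" for i in range(n)}
        truth = {name1[i]: name2[i] for i in range(n)}

        h1 = nx.relabel_nodes(g1, name1)
        h2 = nx.Graph()
        h2.add_nodes_from(name2.values())
        h2.add_edges_from((name2[u], name2[v]) for u, v in g1.edges)
        n_rewire = round(rewire_fraction * h2.number_of_edges())
        if n_rewire:
            edges = sorted(map(tuple, h2.edges))
            drop = rng.choice(len(edges), size=n_rewire, replace=False)
            h2.remove_edges_from(edges[i] for i in drop)
            nodes2 = sorted(h2.nodes)
            added = 0
            while added < n_rewire:
                a, b = rng.integers(n, size=2)
                u, v = nodes2[int(a)], nodes2[int(b)]
                if u != v and not h2.has_edge(u, v):
                    h2.add_edge(u, v)
                    added += 1
        net1 = Network("species_a", h1)
        net2 = Network("species_b", h2)
        params = dict(n=n, density=density, rewire_fraction=rewire_fraction, seed=seed)
        if preprocess_network(net1).n_nodes and preprocess_network(net2).n_nodes:
            return SyntheticPair(net1, net2, truth, params)
    raise GeneratorError(
        "could not generate a pair with nonempty two-core; try a higher density"
    )


def degree_preserving_randomize(net: Network, seed: int) -> Network:
    """Configuration-model rewiring from the exact degree sequence.

    Stub matching realizes the degree sequence, then self loops and parallel
    edges are removed, so individual degrees can drop slightly.
    """
    nodes = net.nodes
    degrees = [net.degree_of(v) for v in nodes]
    multi = nx.configuration_model(degrees, seed=int(seed))
    simple = nx.Graph(multi)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    g = nx.relabel_nodes(simple, dict(enumerate(nodes)))
    g.add_nodes_from(nodes)
    return Network(net.species_tag, g)


def _grow_group(
    graph: nx.Graph,
    start: str,
    remaining: set[str],
    group_size: int,
) -> list[str] | None:
    """One connected neighborhood grown by BFS inside ``remaining``."""
    group = [start]
    frontier = [start]
    while frontier and len(group) < group_size:
        nxt = []
        for u in frontier:
            for w in sorted(graph.neighbors(u)):
                if w in remaining and w not in group:
                    group.append(w)
                    nxt.append(w)
                    if len(group) == group_size:
                        return group
            if len(group) == group_size:
                return group
        frontier = nxt
    return group if len(group) == group_size else None


def _connected_groups(
    graph: nx.Graph,
    eligible: set[str],
    n_groups: int,
    group_size: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Disjoint connected neighborhoods, paired into adjacent couples.

    Even-indexed groups start at a random eligible node; each odd-indexed
    group starts at an eligible neighbor of its couple partner, so the two
    pathways of a couple occupy the same network region — the topological
    footprint of two pathways carrying the same essential function.
    """
    remaining = set(eligible)
    groups: list[list[str]] = []
    order = sorted(remaining)
    rng.shuffle(order)
    cursor = 0
    while len(groups) < n_groups and cursor < len(order):
        start = order[cursor]
        cursor += 1
        if start not in remaining:
            continue
        first = _grow_group(graph, start, remaining, group_size)
        if first is None:
            continue
        # partner pathway grows from the boundary of the first
        boundary = sorted(
            {
                w
                for u in first
                for w in graph.neighbors(u)
                if w in remaining and w not in first
            }
        )
        rng.shuffle(boundary)
        second = None
        trial = set(remaining) - set(first)
        for b_start in boundary:
            second = _grow_group(graph, b_start, trial, group_size)
            if second is not None:
                break
        if second is None:
            continue
        groups.extend([first, second])
        remaining -= set(first) | set(second)
    if len(groups) < n_groups:
        raise GeneratorError(
            f"found only {len(groups)} of {n_groups} connected pathway groups"
        )
    return groups


def plant_sl_interactions(
    pair: SyntheticPair,
    n_pathways: int = 8,
    pathway_size: int = 10,
    seed: int = 0,
    n_pairs_per_class: int = 200,
    negative_mode: str = "random",
) -> tuple[SLDataset, dict[str, int]]:
    """Plant pathway-structured synthetic-lethal labels in both species.

    Pathways are disjoint connected neighborhoods of net1 (carried to net2 by
    the truth map); consecutive pathways (0,1), (2,3), ... form redundant
    couples occupying adjacent network regions.  SLI pairs are sampled within
    pathways and between coupled pathways.  Non-SLI pairs are, by default,
    sampled uniformly from network pairs without an SLI (the construction
    used for benchmark SLI datasets); ``negative_mode="cross_pathway"``
    restricts them to pairs spanning unrelated pathways instead.  Both
    species receive the same gene pairs through the correspondence, so labels
    are cross-species consistent.
    """
    if n_pathways % 2:
        raise GeneratorError("n_pathways must be even (pathways pair into couples)")
    if n_pathways * pathway_size > pair.net1.n_nodes:
        raise GeneratorError("not enough nodes for the requested pathways")
    rng = np.random.default_rng(seed)
    core1 = set(preprocess_network(pair.net1).graph.nodes)
    core2 = set(preprocess_network(pair.net2).graph.nodes)
    eligible = {v for v in core1 if pair.truth[v] in core2}
    groups = _connected_groups(pair.net1.graph, eligible, n_pathways, pathway_size, rng)
    assignment = {v: gi for gi, group in enumerate(groups) for v in group}

    within = [
        p
        for group in groups
        for p in itertools.combinations(sorted(group), 2)
    ]
    between = [
        canonical_pair(u, v)
        for c in range(n_pathways // 2)
        for u in groups[2 * c]
        for v in groups[2 * c + 1]
    ]
    positives_all = sorted(set(within) | set(between))
    if negative_mode == "cross_pathway":
        negatives_all = sorted(
            {
                canonical_pair(u, v)
                for gi, gj in itertools.combinations(range(n_pathways), 2)
                if gi // 2 != gj // 2
                for u in groups[gi]
                for v in groups[gj]
            }
        )
    elif negative_mode == "random":
        pool = sorted(
            set(itertools.combinations(sorted(eligible), 2)) - set(positives_all)
        )
        negatives_all = pool
    else:
        raise GeneratorError(f"unknown negative_mode {negative_mode!r}")
    n_take = min(n_pairs_per_class, len(positives_all), len(negatives_all))
    pos_idx = rng.choice(len(positives_all), size=n_take, replace=False)
    neg_idx = rng.choice(len(negatives_all), size=n_take, replace=False)
    positives = {positives_all[i] for i in pos_idx}
    negatives = {negatives_all[i] for i in neg_idx}

    ds1 = SLDataset.from_pairs(
        pair.net1.species_tag, positives, negatives, provenance="planted pathways"
    )
    map2 = lambda p: canonical_pair(pair.truth[p[0]], pair.truth[p[1]])  # noqa: E731
    ds2 = SLDataset.from_pairs(
        pair.net2.species_tag,
        {map2(p) for p in positives},
        {map2(p) for p in negatives},
        provenance="planted pathways (mapped by truth)",
    )
    return ds1.merge(ds2), assignment


def make_toy_ontology(
    pair: SyntheticPair,
    assignment: dict[str, int],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[OntologyAnnotation, dict[str, PhenotypeGeneMap]]:
    """Toy ontology and phenotype maps correlated with planted pathways.

    The term DAG has a root, one ``process`` term per redundant pathway
    couple (is_a root) and one ``pathway`` term per pathway (is_a its
    process, with a part_of edge to the root for relation-type coverage).
    Every pathway gene is annotated to its pathway term in both species (net2
    genes through the truth map); with probability ``noise`` a gene's
    annotation is redirected to a random pathway term.  Phenotypes, one per
    pathway couple, collect the genes of the couple's two pathways.
    """
    rng = np.random.default_rng(seed)
    n_pathways = max(assignment.values()) + 1
    dag = nx.MultiDiGraph()
    root = "T:root"
    dag.add_node(root)
    path_terms = []
    for p in range(n_pathways):
        proc = f"T:process{p // 2}"
        if proc not in dag:
            dag.add_edge(proc, root, relation="is_a")
        term = f"T:pathway{p}"
        dag.add_edge(term, proc, relation="is_a")
        dag.add_edge(term, root, relation="part_of")
        path_terms.append(term)

    def term_for(p: int) -> str:
        if noise > 0 and rng.random() < noise:
            return path_terms[int(rng.integers(n_pathways))]
        return path_terms[p]

    sp1, sp2 = pair.net1.species_tag, pair.net2.species_tag
    gene_terms: dict[str, dict[str, set[str]]] = {sp1: {}, sp2: {}}
    for gene in sorted(assignment):
        gene_terms[sp1][gene] = {term_for(assignment[gene])}
        gene_terms[sp2][pair.truth[gene]] = {term_for(assignment[gene])}
    ann = OntologyAnnotation(dag, gene_terms)
    ann.validate()

    phenos: dict[str, PhenotypeGeneMap] = {}
    for species, mapper in ((sp1, lambda g: g), (sp2, lambda g: pair.truth[g])):
        mapping = {}
        for c in range(n_pathways // 2):
            genes = [g for g, p in assignment.items() if p // 2 == c]
            if noise > 0:
                n_swap = int(round(noise * len(genes)))
                if n_swap:
                    pool = sorted(set(assignment) - set(genes))
                    out = rng.choice(len(genes), size=n_swap, replace=False)
                    repl = rng.choice(len(pool), size=n_swap, replace=False)
                    for k, (i, j) in enumerate(zip(out, repl)):
                        genes[int(i)] = pool[int(j)]
            mapping[f"pheno{c}"] = frozenset(mapper(g) for g in set(genes))
        phenos[species] = PhenotypeGeneMap(species, mapping)
    return ann, phenos
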