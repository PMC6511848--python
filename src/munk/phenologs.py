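"""Generalized phenolog discovery.

A phenolog is a pair of phenotypes in two species that share a surprising
number of associated genes once genes are mapped between species.  Here the
mapping is not sequence homology but functional similarity: a cross-species
gene pair is "related" when its embedding dissimilarity falls below a
(stringent) threshold.  Target-species gene sets are mapped through that
relation into the source species, overlap with the source phenotype's gene
set is scored by the hypergeometric upper tail, and significance across all
phenotype pairs is controlled by a permutation-based false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom

from .embedding import CrossSpeciesScores

__all__ = [
    "PhenotypeGeneMap",
    "PhenologHit",
    "functional_pair_relation",
    "map_geneset",
    "phenolog_pvalue",
    "phenolog_scan",
    "default_tau",
    "DEFAULT_TAU_QUANTILE",
]

#: quantile of the finite dissimilarity distribution used as the default
#: "functionally similar" threshold (stringent by design)
DEFAULT_TAU_QUANTILE = 0.001


@dataclass(frozen=True)
class PhenotypeGeneMap:
    """phenotype id -> gene set for one species."""

    species_tag: str
    mapping: dict[str, frozenset[str]]

    def __post_init__(self):
        for pheno, genes in self.mapping.items():
            if not genes:
                raise ValueError(f"phenotype {pheno!r} has an empty gene set")

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.mapping)


@dataclass(frozen=True)
class PhenologHit:
    phenotype_a: str
    phenotype_b: str
    overlap_count: int
    pair_count: int  # functionally-similar cross-species pairs (diagnostic)
    p_value: float
    q_value: float


def read_phenotype_map(path, species_tag: str) -> PhenotypeGeneMap:
    """Read a (species, phenotype_id, gene_id) TSV, keeping one species."""
    from .graph_io import InputError, _is_header, _iter_data_lines  # noqa: PLC0415

    mapping: dict[str, set[str]] = {}
    first = True
    for lineno, fields in _iter_data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: expected three columns, got {fields!r}")
        species, pheno, gene = fields[:3]
        if species == species_tag:
            mapping.setdefault(pheno, set()).add(gene)
    if not mapping:
        raise InputError(f"{path}: no phenotypes for species {species_tag!r}")
    return PhenotypeGeneMap(species_tag, {p: frozenset(g) for p, g in mapping.items()})


def default_tau(dissim: CrossSpeciesScores, quantile: float = DEFAULT_TAU_QUANTILE) -> float:
    """Stringent threshold: the given quantile of finite dissimilarities."""
    finite = dissim.values[np.isfinite(dissim.values)]
    if finite.size == 0:
        raise ValueError("no finite dissimilarity scores")
    return float(np.quantile(finite, quantile))


def functional_pair_relation(
    dissim: CrossSpeciesScores, tau: float
) -> dict[str, set[str]]:
    """Binary relation target_gene -> {source genes with dissimilarity <= tau}.

    Monotone in tau: a larger threshold can only add pairs.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rel: dict[str, set[str]] = {}
    rows, cols = np.nonzero(np.isfinite(dissim.values) & (dissim.values <= tau))
    for i, j in zip(rows, cols):
        rel.setdefault(dissim.target_index[j], set()).add(dissim.source_index[i])
    return rel


def map_geneset(relation: Mapping[str, set[str]], geneset_b) -> set[str]:
    """Source genes related to at least one gene of a target-species set."""
    out: set[str] = set()
    for g in geneset_b:
        out |= relation.get(g, set())
    return out


def phenolog_pvalue(
    set_a: set[str], mapped_b: set[str], universe: int
) -> tuple[int, float]:
    """Hypergeometric upper tail P(X >= overlap) for |set_a ∩ mapped_b|.

    Population = universe, successes = |mapped_b|, draws = |set_a|.
    """
    if len(set_a) > universe or len(mapped_b) > universe:
        raise ValueError("set size exceeds the gene universe")
    overlap = len(set_a & mapped_b)
    p = float(hypergeom.sf(overlap - 1, universe, len(mapped_b), len(set_a)))
    return overlap, min(p, 1.0)


def _scan_pvalues(
    map_a: Mapping[str, frozenset[str]],
    map_b: Mapping[str, frozenset[str]],
    relation: Mapping[str, set[str]],
    universe_genes: set[str],
) -> dict[tuple[str, str], tuple[int, int, float]]:
    """(overlap, pair_count, p) for every phenotype pair."""
    n_universe = len(universe_genes)
    mapped_cache = {
        pb: map_geneset(relation, genes) & universe_genes
        for pb, genes in map_b.items()
    }
    # reverse relation restricted to the universe, for the pair-count diagnostic
    results = {}
    for pa in sorted(map_a):
        set_a = set(map_a[pa]) & universe_genes
        for pb in sorted(map_b):
            mapped = mapped_cache[pb]
            overlap, p = phenolog_pvalue(set_a, mapped, n_universe)
            pair_count = sum(
                1
                for gb in map_b[pb]
                for ga in relation.get(gb, ())
                if ga in set_a
            )
            results[(pa, pb)] = (overlap, pair_count, p)
    return results


def _permute_map(
    pmap: Mapping[str, frozenset[str]], genes: list[str], rng: np.random.Generator
) -> dict[str, frozenset[str]]:
    """Relabel genes by a random permutation of the species' gene universe."""
    perm = rng.permutation(len(genes))
    relabel = {g: genes[perm[i]] for i, g in enumerate(genes)}
    return {
        ph: frozenset(relabel.get(g, g) for g in gs) for ph, gs in pmap.items()
    }


def phenolog_scan(
    map_a: PhenotypeGeneMap,
    map_b: PhenotypeGeneMap,
    relation: Mapping[str, set[str]],
    universe_genes: set[str],
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[PhenologHit], list[PhenologHit]]:
    """Score every phenotype pair and estimate permutation-FDR q-values.

    The null rewires gene labels: both maps are relabeled through independent
    random permutations of their species' gene universes and the scan is
    re-run ``n_perm`` times.  For an observed p-value threshold t, q(t) is the
    average null count of pairs with p <= t divided by the observed count,
    made monotone by a running minimum from the largest p down.

    Returns (all results sorted by p, the hits with q <= alpha).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not relation:
        raise ValueError("empty functional-pair relation")
    observed = _scan_pvalues(map_a.mapping, map_b.mapping, relation, universe_genes)
    if not observed:
        raise ValueError("no phenotype pairs to scan")
    rng = np.random.default_rng(seed)
    genes_a = sorted(set().union(*map_a.mapping.values()))
    genes_b = sorted(set().union(*map_b.mapping.values()))
    null_ps: list[float] = []
    for _ in range(n_perm):
        pa = _permute_map(map_a.mapping, genes_a, rng)
        pb = _permute_map(map_b.mapping, genes_b, rng)
        null_ps.extend(p for _, _, p in _scan_pvalues(pa, pb, relation, universe_genes).values())
    null_ps = np.sort(np.asarray(null_ps))

    keys = sorted(observed, key=lambda k: (observed[k][2], k))
    obs_p = np.array([observed[k][2] for k in keys])
    # mean null count at each observed threshold / observed count at it
    null_counts = np.searchsorted(null_ps, obs_p, side="right") / n_perm
    obs_counts = np.arange(1, len(keys) + 1, dtype=float)
    # equal observed p-values must share a q estimate: use the last index of
    # each tie group for the observed count
    obs_counts = np.array(
        [np.searchsorted(obs_p, p, side="right") for p in obs_p], dtype=float
    )
    q_raw = np.minimum(null_counts / obs_counts, 1.0)
    # enforce monotonicity in p
    q = np.minimum.accumulate(q_raw[::-1])[::-1]
    results = [
        PhenologHit(pa, pb, observed[(pa, pb)][0], observed[(pa, pb)][1],
                    observed[(pa, pb)][2], float(qv))
        for (pa, pb), qv in zip(keys, q)
    ]
    hits = [h for h in results if h.q_value <= alpha]
    return results, hits
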