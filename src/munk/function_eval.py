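"""Cross-species functional-similarity evaluation.

Covers: Resnik semantic similarity (information content of the most
informative common ancestor), one-to-one matching by the Hungarian algorithm
with Gene Ontology consistency (GOC, mean Jaccard of term sets over matched
pairs), the k-functional-similarity pair relation with AUPR, the
homolog-vs-other dissimilarity contrast, its degree-preserving permutation
null, and function prediction that pools diffusion scores from several
species through a convex combination of weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import average_precision_score, roc_auc_score

from .embedding import (
    CrossSpeciesScores,
    LandmarkList,
    joint_embedding,
)
from .graph_io import HomologPairs, Network, OntologyAnnotation, term_ancestors
from .kernels import DEFAULT_LAMBDA, KernelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingResult",
    "SimplexWeights",
    "simplex_grid",
    "term_information_content",
    "resnik_terms",
    "resnik_protein",
    "hungarian_match",
    "goc",
    "kfs_labels",
    "aupr",
    "auroc",
    "max_f1",
    "max_f1_over_terms",
    "homolog_score_contrast",
    "degree_null_pvalue",
    "multispecies_predict",
]


# ---------------------------------------------------------------------------
# Resnik semantic similarity


def term_information_content(corpus: Mapping[str, set[str]]) -> dict[str, float]:
    """IC(t) = -ln(fraction of corpus genes annotated to t).

    ``corpus`` maps gene -> propagated term set; a term annotating every gene
    (e.g. the root) has IC 0.
    """
    n = len(corpus)
    if n == 0:
        raise ValueError("empty annotation corpus")
    counts: dict[str, int] = {}
    for terms in corpus.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n) for t, c in counts.items()}


def resnik_terms(
    ann: OntologyAnnotation, ic: Mapping[str, float], t1: str, t2: str
) -> float:
    """Max IC over the common ancestors of two terms (each term is its own
    ancestor here); 0 when no common ancestor carries information."""
    anc1 = {t1} | term_ancestors(ann.term_dag, t1)
    anc2 = {t2} | term_ancestors(ann.term_dag, t2)
    common = anc1 & anc2
    return max((ic.get(t, 0.0) for t in common), default=0.0)


def resnik_protein(
    ann: OntologyAnnotation,
    corpus: Mapping[str, set[str]],
    g1: str,
    g2: str,
) -> float | None:
    """Max Resnik term score over all annotation pairs of two genes.

    Annotations are assumed propagated; returns ``None`` (undefined) for an
    unannotated gene, which callers exclude from rank analyses.
    """
    terms1 = corpus.get(g1, set())
    terms2 = corpus.get(g2, set())
    if not terms1 or not terms2:
        return None
    ic = term_information_content(corpus)
    # with propagated (ancestor-closed) sets the most informative common
    # ancestor over all term pairs is the most informative shared term
    best = 0.0
    for t1 in terms1:
        for t2 in terms2:
            best = max(best, resnik_terms(ann, ic, t1, t2))
    return best


# ---------------------------------------------------------------------------
# Matching and GO consistency


@dataclass(frozen=True)
class MatchingResult:
    """One-to-one map of every node on the smaller side to a distinct node of
    the larger side, stored as (source_node, target_node) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)


def hungarian_match(scores: CrossSpeciesScores) -> MatchingResult:
    """Maximum-total-score assignment of the smaller side to the larger.

    Deterministic: the cost matrix is built in lexicographic index order and
    residual ties are resolved by the solver's fixed index-order scan.
    """
    v = scores.values
    if not np.all(np.isfinite(v)):
        raise ValueError("scores must be finite for matching")
    m, n = v.shape
    if m <= n:
        rows, cols = linear_sum_assignment(-v)
        pairs = [(scores.source_index[i], scores.target_index[j]) for i, j in zip(rows, cols)]
    else:
        rows, cols = linear_sum_assignment(-v.T)
        pairs = [(scores.source_index[j], scores.target_index[i]) for i, j in zip(rows, cols)]
    return MatchingResult(tuple(sorted(pairs)))


def goc(
    match: MatchingResult,
    terms_source: Mapping[str, set[str]],
    terms_target: Mapping[str, set[str]],
) -> float:
    """Mean Jaccard index of (propagated) term sets over matched pairs.

    Pairs where both term sets are empty are excluded from the mean; a pair
    with exactly one empty set contributes 0.
    """
    if len(match) == 0:
        raise ValueError("empty matching")
    vals = []
    for s, t in match.pairs:
        ts = terms_source.get(s, set())
        tt = terms_target.get(t, set())
        if not ts and not tt:
            continue
        vals.append(len(ts & tt) / len(ts | tt))
    if not vals:
        raise ValueError("every matched pair has empty annotation sets")
    return float(np.mean(vals))


def kfs_labels(
    ann1: Mapping[str, set[str]],
    ann2: Mapping[str, set[str]],
    k: int = 100,
) -> dict[tuple[str, str], int]:
    """k-functional-similarity labels for all cross-species gene pairs.

    A pair is labeled 1 iff some term annotates both genes and that term
    annotates at most ``k`` genes in each species.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def counts(ann: Mapping[str, set[str]]) -> dict[str, int]:
        c: dict[str, int] = {}
        for terms in ann.values():
            for t in terms:
                c[t] = c.get(t, 0) + 1
        return c

    c1, c2 = counts(ann1), counts(ann2)
    rare = {t for t in c1 if c1[t] <= k and c2.get(t, k + 1) <= k}
    labels = {}
    for g1, t1 in ann1.items():
        r1 = t1 & rare
        for g2, t2 in ann2.items():
            labels[(g1, g2)] = int(bool(r1 & t2))
    return labels


# ---------------------------------------------------------------------------
# Ranking metrics


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise, ties grouped)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def max_f1(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Maximum F1 over all thresholds of the score ranking (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], y[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    precision = tp / k
    recall = tp / n_pos
    # valid thresholds fall between distinct score values (ties grouped)
    boundary = np.append(s[:-1] != s[1:], True)
    f1 = np.where(tp > 0, 2 * precision * recall / (precision + recall + 1e-300), 0.0)
    return float(f1[boundary].max())


def max_f1_over_terms(
    predictions: Mapping[str, Sequence[tuple[str, float]]],
    truth: Mapping[str, set[str]],
) -> float:
    """Mean over terms of the per-term maximum F1 of a ranked gene list."""
    per_term = []
    for term, ranked in predictions.items():
        true_genes = truth.get(term, set())
        if not true_genes:
            logger.warning("term %s has no truth genes; excluded", term)
            continue
        genes = [g for g, _ in ranked]
        scores = [s for _, s in ranked]
        labels = [int(g in true_genes) for g in genes]
        if sum(labels) == 0:
            per_term.append(0.0)
            continue
        per_term.append(max_f1(scores, labels))
    if not per_term:
        raise ValueError("no term with truth genes")
    return float(np.mean(per_term))


# ---------------------------------------------------------------------------
# Homolog contrast and degree-preserving null


def _evaluation_masks(
    scores: CrossSpeciesScores,
    homologs: HomologPairs,
    landmarks: LandmarkList | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (homolog pairs, other pairs) over the score matrix, with
    every pair touching a landmark node excluded from both groups."""
    src_pos = {v: i for i, v in enumerate(scores.source_index)}
    tgt_pos = {v: i for i, v in enumerate(scores.target_index)}
    keep_row = np.ones(len(scores.source_index), dtype=bool)
    keep_col = np.ones(len(scores.target_index), dtype=bool)
    if landmarks is not None:
        for s, t in landmarks.pairs:
            if s in src_pos:
                keep_row[src_pos[s]] = False
            if t in tgt_pos:
                keep_col[tgt_pos[t]] = False
    eligible = np.outer(keep_row, keep_col)
    hom = np.zeros_like(eligible)
    for s, t in homologs:
        if s in src_pos and t in tgt_pos:
            hom[src_pos[s], tgt_pos[t]] = True
    hom &= eligible
    other = eligible & ~hom
    return hom, other


def homolog_score_contrast(
    dissim: CrossSpeciesScores,
    homologs: HomologPairs,
    landmarks: LandmarkList | None = None,
) -> tuple[float, float, float]:
    """(mean homolog dissimilarity, mean other dissimilarity, their ratio).

    Landmark pairs are excluded from both groups; infinite dissimilarities
    (non-positive raw scores) are dropped from the means.
    """
    hom, other = _evaluation_masks(dissim, homologs, landmarks)
    finite = np.isfinite(dissim.values)
    h_vals = dissim.values[hom & finite]
    o_vals = dissim.values[other & finite]
    if h_vals.size == 0 or o_vals.size == 0:
        raise ValueError("a comparison group is empty")
    mean_h, mean_o = float(h_vals.mean()), float(o_vals.mean())
    return mean_h, mean_o, mean_h / mean_o


def _mean_similarity_diff(
    net1: Network,
    net2: Network,
    homologs: HomologPairs,
    landmarks: LandmarkList,
    lam: float,
) -> float:
    """mean similarity over homolog pairs minus mean over other pairs."""
    _, _, scores = joint_embedding(net1, net2, landmarks, lam=lam)
    hom, other = _evaluation_masks(scores, homologs, landmarks)
    if not hom.any() or not other.any():
        raise ValueError("a comparison group is empty")
    return float(scores.values[hom].mean() - scores.values[other].mean())


def degree_null_pvalue(
    net1: Network,
    net2: Network,
    homologs: HomologPairs,
    landmarks: LandmarkList,
    n_perm: int,
    seed: int,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[float, float, np.ndarray]:
    """Permutation test of the homolog similarity excess against
    degree-preserving network randomizations.

    Both networks are rewired by configuration-model stub matching (degrees
    preserved up to self-loop/multi-edge cleanup), the full embedding pipeline
    is re-run, and the homolog-minus-other mean similarity difference is
    recorded.  Returns (p, observed_diff, null_diffs) with
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    from .synthetic import degree_preserving_randomize  # local to avoid cycle

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = _mean_similarity_diff(net1, net2, homologs, landmarks, lam)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        try:
            r1 = degree_preserving_randomize(net1, int(rng.integers(2**31)))
            r2 = degree_preserving_randomize(net2, int(rng.integers(2**31)))
            null[i] = _mean_similarity_diff(r1, r2, homologs, landmarks, lam)
        except Exception as exc:  # noqa: BLE001 - report which permutation died
            raise RuntimeError(f"pipeline failed on permutation {i}: {exc}") from exc
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return p, observed, null


# ---------------------------------------------------------------------------
# Multi-species function prediction


@dataclass(frozen=True)
class SimplexWeights:
    """Nonnegative per-species weights summing to one."""

    alpha: tuple[float, ...]

    def __post_init__(self):
        if any(a < 0 for a in self.alpha):
            raise ValueError("weights must be nonnegative")
        if abs(sum(self.alpha) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def simplex_grid(n_species: int, step: float) -> list[SimplexWeights]:
    """All weight vectors on the regular simplex grid with the given step."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer")

    def rec(remaining: int, slots: int):
        if slots == 1:
            yield (remaining,)
            return
        for i in range(remaining + 1):
            for rest in rec(remaining - i, slots - 1):
                yield (i, *rest)

    return [SimplexWeights(tuple(i / m for i in combo)) for combo in rec(m, n_species)]


def multispecies_predict(
    self_kernel: KernelMatrix,
    cross_scores: Sequence[CrossSpeciesScores],
    weights: SimplexWeights,
    annotations: Sequence[Mapping[str, set[str]]],
    term: str,
    min_occurrence: int = 2,
    max_occurrence: int = 300,
) -> list[tuple[str, float]] | None:
    """Rank candidate genes of the prediction species for one term.

    ``annotations[0]`` is the prediction species' own gene -> term map (scored
    through the self kernel); ``annotations[1:]`` align with ``cross_scores``
    (each scored through the corresponding cross-species matrix, whose source
    index must be the prediction species).  Each candidate's score is the
    weighted sum over species of its total similarity to the genes annotated
    with the term in that species; annotated seed genes of the prediction
    species are excluded from the candidate list.  Terms whose own-species
    occurrence falls outside [min_occurrence, max_occurrence] are skipped with
    a warning (returns ``None``).
    """
    if len(annotations) != len(cross_scores) + 1:
        raise ValueError("need one annotation map per species (self first)")
    if len(weights.alpha) != len(annotations):
        raise ValueError("one weight per species required")
    own_seeds = [g for g, ts in annotations[0].items() if term in ts]
    if not (min_occurrence <= len(own_seeds) <= max_occurrence):
        logger.warning(
            "term %s occurs %d times in the prediction species "
            "(outside [%d, %d]); skipped", term, len(own_seeds),
            min_occurrence, max_occurrence,
        )
        return None
    nodes = self_kernel.node_index
    pos = {v: i for i, v in enumerate(nodes)}
    total = np.zeros(len(nodes))
    seed_idx = [pos[g] for g in own_seeds if g in pos]
    if weights.alpha[0] > 0 and seed_idx:
        total += weights.alpha[0] * self_kernel.values[:, seed_idx].sum(axis=1)
    for alpha, cross, ann in zip(weights.alpha[1:], cross_scores, annotations[1:]):
        if alpha == 0:
            continue
        if cross.source_index != nodes:
            raise ValueError("cross-score source index must match the self kernel")
        tpos = {v: i for i, v in enumerate(cross.target_index)}
        idx = [tpos[g] for g, ts in ann.items() if term in ts and g in tpos]
        if idx:
            total += alpha * cross.values[:, idx].sum(axis=1)
    seeds = set(own_seeds)
    ranked = sorted(
        ((g, float(total[pos[g]])) for g in nodes if g not in seeds),
        key=lambda gs: (-gs[1], gs[0]),
    )
    return ranked
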