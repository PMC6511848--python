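"""Multi-species synthetic-lethality classification on pair representations.

Gene pairs from the source species are featurized from C1 rows and pairs from
the target species from the C2hat rows; because both embeddings live in the
same space, one classifier (random forest or linear SVM) is trained on pairs
from both species simultaneously.  Cross-validation is stratified jointly by
species and label, the random-forest tree count is chosen per outer fold by
nested inner CV on held-out AUPR, and metrics (AUROC / AUPR / max F1) are
reported separately per species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .embedding import EmbeddingMatrix
from .graph_io import Network
from .function_eval import aupr, auroc, max_f1
from .pairs import canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "SLDataset",
    "CVReport",
    "build_pair_features",
    "sample_negatives",
    "cv_evaluate",
    "holdout_gene_split",
    "TREE_GRID",
    "INNER_FOLDS",
]

#: tree counts searched by the nested CV, and the inner fold count
TREE_GRID = (100, 250, 500)
INNER_FOLDS = 3

SLI = "SLI"
NON_SLI = "non-SLI"


@dataclass(frozen=True)
class SLDataset:
    """Labeled gene pairs per species.

    records: (species_tag, gene_a, gene_b, label) with label in {SLI,
    non-SLI}; pairs are canonicalized (gene_a < gene_b), self-pairs and
    within-species duplicates rejected.
    """

    records: tuple[tuple[str, str, str, str], ...]
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for species, a, b, label in self.records:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) in species {species}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"pair ({a}, {b}) is not in canonical order")
            if label not in (SLI, NON_SLI):
                raise ValueError(f"unknown label {label!r}")
            key = (species, a, b)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_pairs(
        cls,
        species: str,
        positives: set[tuple[str, str]],
        negatives: set[tuple[str, str]],
        provenance: str = "",
    ) -> "SLDataset":
        recs = [(species, *canonical_pair(a, b), SLI) for a, b in sorted(positives)]
        recs += [(species, *canonical_pair(a, b), NON_SLI) for a, b in sorted(negatives)]
        return cls(tuple(sorted(recs)), provenance)

    def merge(self, other: "SLDataset") -> "SLDataset":
        return SLDataset(
            tuple(sorted(self.records + other.records)),
            "; ".join(p for p in (self.provenance, other.provenance) if p),
        )


@dataclass
class CVReport:
    """Per-species, per-fold metrics plus fold averages."""

    per_fold: dict[str, list[dict[str, float]]] = field(default_factory=dict)

    def add(self, species: str, metrics: dict[str, float]) -> None:
        self.per_fold.setdefault(species, []).append(metrics)

    def averages(self) -> dict[str, dict[str, float]]:
        return {
            sp: {
                m: float(np.mean([f[m] for f in folds]))
                for m in folds[0]
            }
            for sp, folds in self.per_fold.items()
        }


def read_sl_tsv(path) -> SLDataset:
    """Read a (species, gene_a, gene_b, label) TSV into an :class:`SLDataset`."""
    from .graph_io import InputError, _is_header, _iter_data_lines  # noqa: PLC0415

    records = []
    first = True
    for lineno, fields in _iter_data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 4:
            raise InputError(f"{path}:{lineno}: expected four columns, got {fields!r}")
        species, a, b, label = fields[:4]
        records.append((species, *canonical_pair(a, b), label))
    return SLDataset(tuple(sorted(set(records))), provenance=str(path))


def build_pair_features(
    C1: EmbeddingMatrix,
    C2hat: EmbeddingMatrix,
    dataset: SLDataset,
    source_species: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, str, str, str]]]:
    """Featurize each labeled pair as the sum of its members' embedding rows.

    Source-species pairs use C1, all other species use C2hat.  Records with a
    gene missing from the relevant embedding are dropped (count logged).
    Returns (X, y, species_tags, kept_records) with y binary (1 = SLI).
    """
    if C1.k != C2hat.k:
        raise ValueError("embeddings do not share a dimension")
    pos1 = {v: i for i, v in enumerate(C1.node_index)}
    pos2 = {v: i for i, v in enumerate(C2hat.node_index)}
    rows, labels, tags, kept = [], [], [], []
    dropped = 0
    for species, a, b, label in dataset.records:
        emb, pos = (C1, pos1) if species == source_species else (C2hat, pos2)
        if a not in pos or b not in pos:
            dropped += 1
            continue
        rows.append(emb.coords[pos[a]] + emb.coords[pos[b]])
        labels.append(1 if label == SLI else 0)
        tags.append(species)
        kept.append((species, a, b, label))
    if dropped:
        logger.warning("%d pairs dropped (gene missing from embedding)", dropped)
    if not rows:
        raise ValueError("no pair survives featurization")
    return np.array(rows), np.array(labels), np.array(tags), kept


def sample_negatives(
    net: Network,
    sli: set[tuple[str, str]],
    n: int,
    seed: int,
) -> set[tuple[str, str]]:
    """Draw n distinct non-SLI node pairs uniformly from the network's node
    set (no self-pairs, none overlapping the SLI set)."""
    sli_canon = {canonical_pair(a, b) for a, b in sli}
    nodes = net.nodes
    eligible = [
        p for p in itertools.combinations(nodes, 2) if p not in sli_canon
    ]
    if n > len(eligible):
        raise ValueError(f"requested {n} negatives but only {len(eligible)} eligible pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return {eligible[i] for i in idx}


def _metric_block(y_true: np.ndarray, y_score: np.ndarray) -> dict[str, float]:
    return {
        "auroc": auroc(y_score, y_true),
        "aupr": aupr(y_score, y_true),
        "max_f1": max_f1(y_score, y_true),
    }


def _fit_and_score(model_name, X_tr, y_tr, X_te, seed, n_trees=None):
    if model_name == "random_forest":
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        clf.fit(X_tr, y_tr)
        return clf.predict_proba(X_te)[:, 1]
    if model_name == "linear_svm":
        clf = LinearSVC(random_state=seed)
        clf.fit(X_tr, y_tr)
        return clf.decision_function(X_te)
    raise ValueError(f"unknown model {model_name!r}")


def _choose_trees(X, y, strata, seed) -> int:
    """Inner nested CV: pick the tree count maximizing mean held-out AUPR."""
    inner = StratifiedKFold(n_splits=INNER_FOLDS, shuffle=True, random_state=seed)
    best, best_score = TREE_GRID[0], -np.inf
    for n_trees in TREE_GRID:
        scores = []
        for tr, te in inner.split(X, strata):
            y_score = _fit_and_score("random_forest", X[tr], y[tr], X[te], seed, n_trees)
            scores.append(aupr(y_score, y[te]))
        mean = float(np.mean(scores))
        if mean > best_score:
            best, best_score = n_trees, mean
    return best


def cv_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    species_tags: np.ndarray,
    model: str = "random_forest",
    n_folds: int = 4,
    seed: int = 0,
) -> CVReport:
    """Cross-validate one classifier on pairs from both species jointly.

    Folds are stratified by (species, label) so the per-species class mix is
    fixed across folds; metrics are computed on held-out pairs separately per
    species and averaged over folds by :meth:`CVReport.averages`.
    """
    species = sorted(set(species_tags))
    if len(species) < 1:
        raise ValueError("no species in dataset")
    strata = np.array([f"{s}|{l}" for s, l in zip(species_tags, labels)])
    for stratum, count in zip(*np.unique(strata, return_counts=True)):
        if count < n_folds:
            raise ValueError(
                f"stratum {stratum} has {count} < {n_folds} pairs; "
                "stratified folds impossible"
            )
    for sp in species:
        if len(set(labels[species_tags == sp])) < 2:
            raise ValueError(f"species {sp} lacks one of the two classes")
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    report = CVReport()
    for tr, te in outer.split(features, strata):
        n_trees = None
        if model == "random_forest":
            n_trees = _choose_trees(features[tr], labels[tr], strata[tr], seed)
        y_score = _fit_and_score(model, features[tr], labels[tr], features[te], seed, n_trees)
        for sp in species:
            m = species_tags[te] == sp
            report.add(sp, _metric_block(labels[te][m], y_score[m]))
    return report


def holdout_gene_split(
    dataset: SLDataset,
    fraction: float,
    seed: int,
) -> tuple[list[tuple[str, str, str, str]], list[tuple[str, str, str, str]]]:
    """Hold out a fraction of genes per species; every pair touching a
    held-out gene goes to the test side, pairs of only-training genes to the
    train side."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    held: dict[str, set[str]] = {}
    by_species: dict[str, set[str]] = {}
    for species, a, b, _ in dataset.records:
        by_species.setdefault(species, set()).update((a, b))
    for species, genes in sorted(by_species.items()):
        genes = sorted(genes)
        n_held = max(1, int(round(fraction * len(genes))))
        idx = rng.choice(len(genes), size=n_held, replace=False)
        held[species] = {genes[i] for i in idx}
    train, test = [], []
    for rec in dataset.records:
        species, a, b, _ = rec
        if a in held[species] or b in held[species]:
            test.append(rec)
        else:
            train.append(rec)
    if not train or not test:
        raise ValueError("degenerate hold-out split (empty train or test)")
    return train, test
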