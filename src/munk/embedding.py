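"""Joint embedding of two networks in one reproducing kernel Hilbert space.

The source kernel D1 is factorized as D1 = C1 C1^T (rows of C1 are the source
node coordinates; the factorization is unique only up to an orthogonal
rotation, and every downstream score is invariant to that rotation).  A set of
landmark homolog pairs anchors the target network: writing C1L for the
landmark rows of C1 and D2L for the landmark rows of the target kernel D2, the
target coordinates solve the underdetermined system

    C1L @ C2hat^T = D2L

and we take the minimum-Frobenius-norm solution C2hat^T = pinv(C1L) @ D2L.
Cross-species similarity scores are then D12 = C1 @ C2hat^T; their reciprocals
serve as dissimilarities (small = functionally close).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph_io import HomologPairs, Network
from .kernels import KernelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "LandmarkList",
    "CrossSpeciesScores",
    "factorize_kernel",
    "select_landmarks",
    "embed_target",
    "cross_species_scores",
    "joint_embedding",
    "to_dissimilarity",
    "DEFAULT_N_LANDMARKS",
]

#: default number of landmark pairs
DEFAULT_N_LANDMARKS = 400

_EIG_DROP = 1e-10     # eigenvalues below this are treated as zero rank
_PSD_TOL = -1e-8
_PINV_RCOND = 1e-12   # relative singular-value cutoff for the pseudoinverse


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-node RKHS coordinates: one row per node, k columns."""

    node_index: tuple[str, ...]
    coords: np.ndarray
    source_flag: bool  # True for factorized (C1), False for solved (C2hat)

    def __post_init__(self):
        if self.coords.shape[0] != len(self.node_index):
            raise ValueError("coordinate rows do not match node index")

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def row(self, node: str) -> np.ndarray:
        return self.coords[self.node_index.index(node)]


@dataclass(frozen=True)
class LandmarkList:
    """Ordered (source_node, target_node) anchor pairs; the order defines the
    shared row order of C1L and D2L."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("landmark list may not be empty")
        src = [s for s, _ in self.pairs]
        tgt = [t for _, t in self.pairs]
        if len(set(src)) != len(src) or len(set(tgt)) != len(tgt):
            raise ValueError("landmark nodes may not repeat")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source_nodes(self) -> list[str]:
        return [s for s, _ in self.pairs]

    @property
    def target_nodes(self) -> list[str]:
        return [t for _, t in self.pairs]


@dataclass(frozen=True)
class CrossSpeciesScores:
    """m x n matrix of scores between source rows and target columns."""

    source_index: tuple[str, ...]
    target_index: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.source_index), len(self.target_index)):
            raise ValueError("score matrix shape does not match indices")

    def score(self, source_node: str, target_node: str) -> float:
        return float(
            self.values[
                self.source_index.index(source_node),
                self.target_index.index(target_node),
            ]
        )


def factorize_kernel(K: KernelMatrix) -> EmbeddingMatrix:
    """Factorize K = C C^T by eigendecomposition.

    Columns are ordered by descending eigenvalue; eigenvalues below 1e-10 are
    dropped (defining k); each column's sign is fixed so its largest-magnitude
    entry is positive.
    """
    w, v = np.linalg.eigh(K.values)
    if w.min() < _PSD_TOL:
        raise ValueError(f"matrix is not a kernel (eigenvalue {w.min():g} < 0)")
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > _EIG_DROP
    w, v = w[keep], v[:, keep]
    coords = v * np.sqrt(w)
    # deterministic sign convention per column
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    coords = coords * signs
    return EmbeddingMatrix(K.node_index, coords, source_flag=True)


def select_landmarks(
    candidates: HomologPairs,
    n_landmarks: int,
    strategy: str,
    seed: int,
    net1: Network,
    net2: Network,
) -> LandmarkList:
    """Choose landmark pairs from the homolog candidates.

    ``random`` draws without replacement under the seed.  ``degree`` sorts
    candidates by the average of their within-species degree ranks (rank 1 =
    highest degree), ties broken by lexicographic source id, and takes the top
    ``n_landmarks``.
    """
    pairs = list(candidates.pairs)
    if n_landmarks > len(pairs):
        raise ValueError(
            f"requested {n_landmarks} landmarks but only {len(pairs)} candidates"
        )
    if strategy == "random":
        rng = np.random.default_rng(seed)
        chosen = [pairs[i] for i in rng.choice(len(pairs), n_landmarks, replace=False)]
    elif strategy == "degree":
        def rank_map(net: Network, nodes: list[str]) -> dict[str, float]:
            # rank 1 = highest degree; average rank over ties
            degs = sorted(((-net.degree_of(v), v) for v in nodes))
            return {v: i + 1 for i, (_, v) in enumerate(degs)}

        r1 = rank_map(net1, [s for s, _ in pairs])
        r2 = rank_map(net2, [t for _, t in pairs])
        scored = sorted(pairs, key=lambda p: ((r1[p[0]] + r2[p[1]]) / 2.0, p[0]))
        chosen = scored[:n_landmarks]
    else:
        raise ValueError(f"unknown landmark strategy {strategy!r}")
    return LandmarkList(tuple(chosen))


def embed_target(
    C1: EmbeddingMatrix, D2: KernelMatrix, landmarks: LandmarkList
) -> EmbeddingMatrix:
    """Solve the landmark system for the target coordinates (minimum norm).

    C2hat^T = pinv(C1L) @ D2L, the W = 0 member of the solution family
    C2hat^T = pinv(C1L) @ D2L + (I - pinv(C1L) @ C1L) @ W.
    """
    src_pos = {v: i for i, v in enumerate(C1.node_index)}
    tgt_pos = {v: i for i, v in enumerate(D2.node_index)}
    c1l = C1.coords[[src_pos[s] for s in landmarks.source_nodes]]
    d2l = D2.values[[tgt_pos[t] for t in landmarks.target_nodes]]
    sv = np.linalg.svd(c1l, compute_uv=False)
    if sv.size and sv[-1] <= _PINV_RCOND * sv[0]:
        logger.warning(
            "landmark coordinate matrix is near-singular "
            "(condition %.3g); pseudoinverse cutoff applied", sv[0] / max(sv[-1], 1e-300)
        )
    c2hat_t = np.linalg.pinv(c1l, rcond=_PINV_RCOND) @ d2l
    return EmbeddingMatrix(D2.node_index, c2hat_t.T, source_flag=False)


def cross_species_scores(
    C1: EmbeddingMatrix, C2hat: EmbeddingMatrix
) -> CrossSpeciesScores:
    """Similarity scores D12 = C1 @ C2hat^T between all cross-species pairs."""
    if C1.k != C2hat.k:
        raise ValueError(f"dimension mismatch: k={C1.k} vs k={C2hat.k}")
    return CrossSpeciesScores(C1.node_index, C2hat.node_index, C1.coords @ C2hat.coords.T)


def joint_embedding(
    net1: Network,
    net2: Network,
    landmarks: LandmarkList,
    lam: float | None = None,
) -> tuple[EmbeddingMatrix, EmbeddingMatrix, CrossSpeciesScores]:
    """End-to-end convenience: kernels for both networks, factorize the
    source, solve the target, and return (C1, C2hat, D12)."""
    from .kernels import DEFAULT_LAMBDA, regularized_laplacian

    lam = DEFAULT_LAMBDA if lam is None else lam
    d1 = regularized_laplacian(net1, lam)
    d2 = regularized_laplacian(net2, lam)
    c1 = factorize_kernel(d1)
    c2hat = embed_target(c1, d2, landmarks)
    return c1, c2hat, cross_species_scores(c1, c2hat)


def to_dissimilarity(scores: CrossSpeciesScores) -> CrossSpeciesScores:
    """Reciprocal scores: s -> 1/s for s > 0, +inf otherwise.

    Diffusion scores can come out non-positive after the landmark solve; their
    reciprocal is undefined, so they map to an infinite dissimilarity (never
    functionally close).  The ordering of positive scores is exactly reversed.
    """
    v = scores.values
    out = np.full_like(v, np.inf, dtype=float)
    pos = v > 0
    out[pos] = 1.0 / v[pos]
    return CrossSpeciesScores(scores.source_index, scores.target_index, out)
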