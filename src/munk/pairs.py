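"""Gene-pair representations: the sum of the two members' embedding rows.

Pair similarity is the plain inner product, which expands as

    (c_i + c_j)^T (c_k + c_l) = c_i^T c_k + c_i^T c_l + c_j^T c_k + c_j^T c_l

so two pairs score highly only when their members are cross-wise similar —
the geometry that makes within-pathway / redundant-pathway gene pairs
(synthetic-lethal candidates) co-locate in the embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingMatrix

__all__ = ["PairVector", "pair_representation", "pair_score", "canonical_pair"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Sorted pair key, so pair sets deduplicate deterministically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairVector:
    gene_a: str
    gene_b: str
    vector: np.ndarray


def pair_representation(C: EmbeddingMatrix, i: str, j: str) -> PairVector:
    """Vector for the pair (i, j): row(i) + row(j).  Symmetric in (i, j)."""
    a, b = canonical_pair(i, j)
    return PairVector(a, b, C.row(i) + C.row(j))


def pair_score(p: PairVector, q: PairVector) -> float:
    """Inner product of two pair vectors."""
    if p.vector.shape != q.vector.shape:
        raise ValueError(
            f"dimension mismatch: {p.vector.shape} vs {q.vector.shape}"
        )
    return float(np.dot(p.vector, q.vector))
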