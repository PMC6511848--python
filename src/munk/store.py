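"""HDF5 persistence (with TSV export) for kernels, embeddings and scores."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .embedding import CrossSpeciesScores, EmbeddingMatrix
from .kernels import KernelMatrix

__all__ = [
    "save_kernel", "load_kernel",
    "save_embedding", "load_embedding",
    "save_scores", "load_scores",
    "scores_to_tsv", "kernel_to_tsv",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_index(group: h5py.Group, name: str, index) -> None:
    group.create_dataset(name, data=np.array(list(index), dtype=_STR), track_times=False)


def _read_index(group: h5py.Group, name: str) -> tuple[str, ...]:
    return tuple(s.decode() if isinstance(s, bytes) else s for s in group[name][()])


def save_kernel(path, kernel: KernelMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=kernel.values, track_times=False)
        _write_index(f, "node_index", kernel.node_index)
        f.attrs["lambda"] = kernel.lambda_used


def load_kernel(path) -> KernelMatrix:
    with h5py.File(path, "r") as f:
        return KernelMatrix(
            _read_index(f, "node_index"), f["values"][()], float(f.attrs["lambda"])
        )


def save_embedding(path, emb: EmbeddingMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=emb.coords, track_times=False)
        _write_index(f, "node_index", emb.node_index)
        f.attrs["source_flag"] = emb.source_flag


def load_embedding(path) -> EmbeddingMatrix:
    with h5py.File(path, "r") as f:
        return EmbeddingMatrix(
            _read_index(f, "node_index"), f["coords"][()], bool(f.attrs["source_flag"])
        )


def save_scores(path, scores: CrossSpeciesScores) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=scores.values, track_times=False)
        _write_index(f, "source_index", scores.source_index)
        _write_index(f, "target_index", scores.target_index)


def load_scores(path) -> CrossSpeciesScores:
    with h5py.File(path, "r") as f:
        return CrossSpeciesScores(
            _read_index(f, "source_index"),
            _read_index(f, "target_index"),
            f["values"][()],
        )


def scores_to_tsv(path, scores: CrossSpeciesScores) -> None:
    pd.DataFrame(
        scores.values, index=list(scores.source_index), columns=list(scores.target_index)
    ).to_csv(Path(path), sep="\t")


def kernel_to_tsv(path, kernel: KernelMatrix) -> None:
    pd.DataFrame(
        kernel.values, index=list(kernel.node_index), columns=list(kernel.node_index)
    ).to_csv(Path(path), sep="\t")
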