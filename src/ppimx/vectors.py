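"""Word-vector file I/O (word2vec text format: header ``n dim`` then one
``word v1 ... vdim`` line per word)."""

from __future__ import annotations

import numpy as np

__all__ = ["load_word_vectors", "save_word_vectors"]


def load_word_vectors(path: str) -> dict[str, np.ndarray]:
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec text format requires an 'n dim' header")
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"bad vector line for {parts[0]!r}")
            vectors[parts[0]] = np.array(parts[1:], dtype=np.float64)
    if len(vectors) != n:
        raise ValueError(f"header promised {n} vectors, found {len(vectors)}")
    return vectors


def save_word_vectors(path: str, vectors: dict[str, np.ndarray]) -> None:
    words = list(vectors)
    dim = len(vectors[words[0]]) if words else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {dim}\n")
        for w in words:
            vals = " ".join(f"{v:.6f}" for v in vectors[w])
            fh.write(f"{w} {vals}\n")
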