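"""Text embeddings for proxy-based answer selection.

The selection step only needs a deterministic map from short answer strings
to fixed-length vectors under which lexically closer answers are nearer.
The default embedder hashes character n-grams (3-5) into a fixed-width
count vector.  Counts are deliberately left unnormalised so that Euclidean
distance remains sensitive to answer length -- the property that makes it
preferable to cosine similarity for picking the most concise relevant
candidate.  Sentence-transformer or masked-LM encoders can be plugged in
through the same one-method contract.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer


class EmbedderContract(Protocol):
    def embed(self, text: str) -> np.ndarray: ...


class HashingNgramEmbedder:
    """Deterministic character n-gram hashing embedder."""

    def __init__(self, n_features: int = 512, ngram_range: tuple[int, int] = (3, 5)):
        self._vec = HashingVectorizer(
            analyzer="char_wb",
            ngram_range=ngram_range,
            n_features=n_features,
            norm=None,
            alternate_sign=False,
            lowercase=True,
        )
        self.n_features = n_features

    def embed(self, text: str) -> np.ndarray:
        return np.asarray(self._vec.transform([text]).todense()).ravel()


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 1.0
    return 1.0 - float(a @ b) / (na * nb)
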