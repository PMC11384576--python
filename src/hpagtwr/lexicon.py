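"""Health-lexicon construction by embedding-based seed expansion.

A small seed set of health words is expanded by training continuous
bag-of-words (CBOW) word embeddings on a corpus and ranking non-seed
vocabulary words by their cosine similarity to the seeds; a curation step
(an explicit accept list, standing in for expert review) fixes the final
lexicon. The CBOW model predicts a center word from the average of its
context-word vectors, trained with negative sampling; words sharing contexts
acquire nearby vectors, so distributional synonyms of the seeds surface at
the top of the ranking.

The trainer here is a compact single-threaded numpy implementation:
training is strictly sequential and seeded, so identical inputs yield
bit-identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidArgumentError, LookupError_, TrainingError

__all__ = [
    "EmbeddingTable",
    "Lexicon",
    "train_embeddings",
    "cosine_similarity",
    "expand_seed_set",
    "curate_lexicon",
]


# --------------------------------------------------------------------------
# embeddings
# --------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Trained word vectors with their vocabulary and training metadata."""

    words: list[str]
    vectors: np.ndarray  # (n_words, dim)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vectors.ndim != 2 or len(self.words) != self.vectors.shape[0]:
            raise InvalidArgumentError("one vector per vocabulary word required")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise LookupError_(f"word {word!r} not in vocabulary") from None

    def save_word2vec_text(self, path: str | Path) -> None:
        """Write the standard word2vec text format: header 'n dim', then rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, vec in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec_text(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vectors = np.asarray(rows, dtype=float)
        if len(words) != n or vectors.shape[1] != dim:
            raise InvalidArgumentError("embedding file header disagrees with body")
        return cls(words=words, vectors=vectors)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    epochs: int = 20,
    min_count: int = 5,
    seed: int = 0,
    *,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 0.0001,
) -> EmbeddingTable:
    """Train CBOW word vectors with negative sampling.

    Words occurring fewer than ``min_count`` times are dropped from the
    vocabulary. The learning rate decays linearly from ``alpha`` to
    ``min_alpha`` over all updates. Training is single-threaded by design:
    with a fixed seed the result is reproducible bit-for-bit.
    """
    if dim < 2:
        raise InvalidArgumentError("embedding dimension must be >= 2")
    sentences = [list(s) for s in corpus if len(s) > 0]
    if not sentences:
        raise TrainingError("corpus is empty")

    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    # deterministic vocabulary order: frequency desc, then lexicographic
    vocab = sorted((w for w, c in counts.items() if c >= min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        raise TrainingError(
            f"no word reaches min_count={min_count}; most frequent word occurs "
            f"{max(counts.values())} time(s)")
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    cum = np.cumsum(freq / freq.sum())

    rng = np.random.default_rng(seed)
    Win = (rng.random((V, dim)) - 0.5) / dim  # input (context) vectors
    Wout = np.zeros((V, dim))  # output (center) vectors

    encoded = [[index[w] for w in sent if w in index] for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    if not encoded:
        raise TrainingError("no sentence retains >= 2 in-vocabulary words")

    total_updates = epochs * sum(len(s) for s in encoded)
    done = 0
    for _ in range(epochs):
        for sent in encoded:
            n = len(sent)
            for pos, center in enumerate(sent):
                lr = alpha - (alpha - min_alpha) * (done / max(total_updates - 1, 1))
                done += 1
                lo, hi = max(0, pos - window), min(n, pos + window + 1)
                ctx = sent[lo:pos] + sent[pos + 1:hi]
                if not ctx:
                    continue
                h = Win[ctx].mean(axis=0)
                # center word is the positive target; negatives drawn from
                # the unigram^0.75 table (collisions with the target allowed,
                # as in standard implementations, but skipped here)
                negs = np.searchsorted(cum, rng.random(negative))
                targets = np.concatenate(([center], negs[negs != center]))
                labels = np.zeros(len(targets)); labels[0] = 1.0
                out = Wout[targets]
                g = (labels - _sigmoid(out @ h)) * lr
                grad_h = g @ out
                Wout[targets] += np.outer(g, h)
                Win[ctx] += grad_h
    return EmbeddingTable(
        words=vocab,
        vectors=Win,
        metadata={"dim": dim, "window": window, "epochs": epochs,
                  "min_count": min_count, "seed": seed, "negative": negative,
                  "alpha": alpha, "model": "cbow-negative-sampling"},
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a||b|), in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("vectors must share a dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise InvalidArgumentError("cosine similarity undefined for zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# --------------------------------------------------------------------------
# expansion and curation
# --------------------------------------------------------------------------


def expand_seed_set(
    embeddings: EmbeddingTable,
    seeds: Iterable[str],
    top_k: int,
    min_similarity: float = -1.0,
) -> list[tuple[str, float, str]]:
    """Rank non-seed vocabulary words by max cosine similarity to any seed.

    Returns ``[(word, score, nearest_seed), ...]`` sorted by descending score
    with lexicographic tie-break, truncated to ``top_k`` entries with
    score >= ``min_similarity``. The score is the *maximum* over seeds: a
    word strongly tied to even one health seed is treated as health-related.
    """
    seeds = set(seeds)
    in_vocab = sorted(s for s in seeds if s in embeddings)
    if not in_vocab:
        raise LookupError_(
            f"no seed present in the vocabulary; missing: {sorted(seeds)}")
    if top_k <= 0:
        return []

    S = np.stack([embeddings.vector(s) for s in in_vocab])  # (m, d)
    S_norm = S / np.linalg.norm(S, axis=1, keepdims=True)
    cand_words = [w for w in embeddings.words if w not in seeds]
    C = np.stack([embeddings.vector(w) for w in cand_words])
    norms = np.linalg.norm(C, axis=1)
    norms[norms == 0] = np.nan  # zero vectors are unqueryable
    sims = (C / norms[:, None]) @ S_norm.T  # (n_cand, m)
    best = np.nanargmax(sims, axis=1)
    scores = sims[np.arange(len(cand_words)), best]

    ranked = sorted(
        ((w, float(np.clip(sc, -1, 1)), in_vocab[bi])
         for w, sc, bi in zip(cand_words, scores, best) if np.isfinite(sc)),
        key=lambda item: (-item[1], item[0]),
    )
    return [r for r in ranked if r[1] >= min_similarity][:top_k]


@dataclass
class Lexicon:
    """Seed words plus curated expansion with per-word provenance."""

    seeds: frozenset[str]
    expanded: dict[str, tuple[float, str]]  # word -> (score, nearest_seed)
    curated: frozenset[str]

    def __post_init__(self):
        if not self.seeds <= self.curated:
            raise InvalidArgumentError("seeds must be contained in the curated set")
        if self.seeds & set(self.expanded):
            raise InvalidArgumentError("expanded words must not repeat seeds")

    def __contains__(self, word: str) -> bool:
        return word in self.curated

    def __len__(self) -> int:
        return len(self.curated)

    def provenance(self, word: str) -> dict:
        if word in self.seeds:
            return {"word": word, "origin": "seed"}
        if word in self.expanded:
            score, nearest = self.expanded[word]
            return {"word": word, "origin": "expanded", "score": score,
                    "nearest_seed": nearest}
        raise LookupError_(f"{word!r} not in lexicon")

    def save(self, path: str | Path) -> None:
        """One curated word per line, UTF-8, sorted."""
        Path(path).write_text("\n".join(sorted(self.curated)) + "\n",
                              encoding="utf-8")

    @staticmethod
    def load_words(path: str | Path) -> list[str]:
        return [w for w in Path(path).read_text(encoding="utf-8").splitlines()
                if w.strip()]


def curate_lexicon(
    seeds: Iterable[str],
    candidates: Sequence[tuple[str, float, str]],
    accept: Iterable[str],
) -> Lexicon:
    """Fix the final lexicon as seeds plus an accepted subset of candidates.

    ``accept`` stands in for expert verification of the expanded list; every
    accepted word must actually appear among the candidates.
    """
    seeds = frozenset(seeds)
    accept = set(accept)
    cand_map = {w: (score, nearest) for w, score, nearest in candidates}
    unknown = sorted(accept - set(cand_map))
    if unknown:
        raise InvalidArgumentError(
            f"accepted words not among candidates: {unknown}")
    expanded = {w: cand_map[w] for w in sorted(accept)}
    return Lexicon(seeds=seeds, expanded=expanded,
                   curated=frozenset(seeds | accept))
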