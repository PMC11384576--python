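"""Health policy attention (HPA) scoring.

The HPA index of a government document is the share of its total term
frequency contributed by a curated health lexicon, multiplied by 100 —
a percent on [0, 100]. Counting token occurrences (not unique types) in
both numerator and denominator makes the score a term-frequency proportion,
invariant to document length and token order. No stop-word removal is
applied: the denominator is the full document as tokenized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["DocumentRecord", "tokenize", "compute_hpa", "score_corpus"]


@dataclass
class DocumentRecord:
    """One (city, year) document, post-tokenization."""

    city_id: int
    year: int
    tokens: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, int]:
        return (self.city_id, self.year)


def tokenize(text: str, segmenter: Callable[[str], list[str]] | None = None
             ) -> list[str]:
    """Split ``text`` into tokens.

    Default mode lowercases and splits on runs of whitespace. A custom
    ``segmenter`` callable (e.g. a Chinese word segmenter) may be injected;
    it receives the raw text and must return a token list.
    """
    if segmenter is not None:
        return list(segmenter(text))
    return text.lower().split()


def compute_hpa(tokens: Sequence[str], lexicon) -> float:
    """Percent of token occurrences that belong to the lexicon.

    ``lexicon`` is any word container supporting ``in`` (a set, or a
    :class:`hpagtwr.lexicon.Lexicon`, whose membership is its curated set).
    """
    if len(tokens) == 0:
        raise InvalidArgumentError("cannot score an empty document (zero denominator)")
    words = getattr(lexicon, "curated", lexicon)
    hits = sum(1 for tok in tokens if tok in words)
    return 100.0 * hits / len(tokens)


def score_corpus(
    documents: Iterable[DocumentRecord],
    lexicon,
    *,
    merge_duplicates: bool = True,
    expected_keys: Iterable[tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Score a corpus into a ``(city_id, year, hpa)`` table.

    Multiple documents sharing a (city_id, year) key are concatenated before
    scoring when ``merge_duplicates`` is true; otherwise duplicate keys raise.
    If ``expected_keys`` is given, keys with no document are returned as the
    second element (reported, never silently dropped).
    """
    pooled: dict[tuple[int, int], list[str]] = {}
    for doc in documents:
        if doc.key in pooled and not merge_duplicates:
            raise KeyError(f"duplicate document key {doc.key} with merging disabled")
        pooled.setdefault(doc.key, []).extend(doc.tokens)

    rows = [(cid, yr, compute_hpa(toks, lexicon))
            for (cid, yr), toks in sorted(pooled.items())]
    table = pd.DataFrame(rows, columns=["city_id", "year", "hpa"])

    missing: list[tuple[int, int]] = []
    if expected_keys is not None:
        missing = sorted(set(expected_keys) - set(pooled))
    return table, missing
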