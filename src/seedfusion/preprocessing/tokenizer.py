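"""Deterministic word-piece style tokenizer.

A minimal tokenizer sufficient for the synthetic corpus: text is lowercased
and stripped of special symbols, split on whitespace, and looked up in a
vocabulary built from a corpus.  Out-of-vocabulary words fall back to
character pieces (``c``, ``##h``, ...), so the tokenizer is total over any
ASCII input.  Sequences are framed by ``[CLS]``/``[SEP]`` and padded or
truncated to a fixed length of 77 ids; a pre-trained tokenizer with the
same interface can be plugged in instead.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass

import numpy as np

__all__ = ["Vocabulary", "TokenizedText", "clean_text", "tokenize",
           "MAX_TEXT_LEN"]

MAX_TEXT_LEN = 77
PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"

_CLEAN_RE = re.compile(r"[^a-z0-9\s-]+")
_WS_RE = re.compile(r"\s+")


def clean_text(text: str) -> str:
    """Lowercase, strip special symbols, collapse whitespace."""
    text = _CLEAN_RE.sub(" ", text.lower())
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class TokenizedText:
    token_ids: np.ndarray       # (max_len,) int64
    attention_mask: np.ndarray  # (max_len,) {0, 1}

    def __post_init__(self):
        mask = self.attention_mask
        n = int(mask.sum())
        if n < 2:
            raise ValueError("mask must cover at least [CLS] and [SEP]")
        if mask[:n].min() != 1 or (len(mask) > n and mask[n:].max() != 0):
            raise ValueError("mask must be a prefix of ones")


class Vocabulary:
    """Word vocabulary with character-piece fallback."""

    def __init__(self, words: list[str]):
        chars = [c for c in string.ascii_lowercase + string.digits + "-"]
        pieces = ([PAD, CLS, SEP, UNK] + chars + [f"##{c}" for c in chars]
                  + sorted(set(words) - set(chars)))
        self._id = {tok: i for i, tok in enumerate(pieces)}
        self._tok = pieces

    @classmethod
    def from_corpus(cls, texts: list[str]) -> "Vocabulary":
        words: set[str] = set()
        for text in texts:
            words.update(clean_text(text).split())
        return cls(sorted(words))

    def __len__(self) -> int:
        return len(self._tok)

    @property
    def pad_id(self) -> int:
        return self._id[PAD]

    @property
    def cls_id(self) -> int:
        return self._id[CLS]

    @property
    def sep_id(self) -> int:
        return self._id[SEP]

    def encode_word(self, word: str) -> list[int]:
        if word in self._id:
            return [self._id[word]]
        pieces = []
        for i, ch in enumerate(word):
            tok = ch if i == 0 else f"##{ch}"
            pieces.append(self._id.get(tok, self._id[UNK]))
        return pieces

    def lookup(self, token_id: int) -> str:
        return self._tok[token_id]


def tokenize(text: str, vocab: Vocabulary,
             max_len: int = MAX_TEXT_LEN) -> TokenizedText:
    """Serialize ``text`` to fixed-length ids framed by [CLS]/[SEP].

    Raises ``ValueError`` when the text is empty after cleanup.
    """
    cleaned = clean_text(text)
    if not cleaned:
        raise ValueError("text is empty after cleanup")
    ids = [vocab.cls_id]
    for word in cleaned.split():
        ids.extend(vocab.encode_word(word))
    ids = ids[:max_len - 1] + [vocab.sep_id]
    mask = np.zeros(max_len, dtype=np.int64)
    mask[:len(ids)] = 1
    padded = np.full(max_len, vocab.pad_id, dtype=np.int64)
    padded[:len(ids)] = ids
    return TokenizedText(token_ids=padded, attention_mask=mask)
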