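"""Subword tokenizer with a fixed vocabulary size.

A byte-pair-encoding tokenizer trained on raw corpus sentences.  The
vocabulary size s (default 500) is fixed before language-model training, which
keeps the model independent of the openness of the (German) clinical
vocabulary: any word, seen or not, decomposes into known subword pieces, with
character-level fallback inside the model and an explicit unknown token only
for characters never seen in training.

Words are marked with a leading ``▁`` (lower one-eighth block), the usual
whitespace marker, so decoding is the exact inverse of encoding for any text
over the training character set.
"""

from __future__ import annotations

import json
import unicodedata
from collections import Counter
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

WORD_BOUNDARY = "▁"

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<bos>", "<eos>"
KW_MARK, KW_SEP, BLOCK_SEP, RPT = "<kw>", "<kwsep>", "<sep>", "<START_REPORT>"

#: Default special tokens, occupying ids 0..7 in this order: padding, unknown,
#: begin/end of sentence, keyword-block marker, keyword delimiter, block
#: separator (keywords | initial sentence), report-start placeholder.
DEFAULT_SPECIAL_TOKENS = [PAD, UNK, BOS, EOS, KW_MARK, KW_SEP, BLOCK_SEP, RPT]


class TokenizerError(ValueError):
    pass


class TokenizerConfig(BaseModel):
    vocab_size: int = 500
    special_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_SPECIAL_TOKENS))

    @model_validator(mode="after")
    def _check(self) -> "TokenizerConfig":
        if self.vocab_size <= len(self.special_tokens):
            raise TokenizerError("vocab_size must exceed the number of special tokens")
        if len(set(self.special_tokens)) != len(self.special_tokens):
            raise TokenizerError("special tokens must be distinct")
        return self


class SubwordVocabulary(BaseModel):
    """Trained piece inventory: ids 0..s-1, specials first, then single
    characters, then merged pieces in merge order."""

    pieces: list[str]
    merges: list[tuple[str, str]]
    config: TokenizerConfig

    @model_validator(mode="after")
    def _check(self) -> "SubwordVocabulary":
        if len(self.pieces) != self.config.vocab_size:
            raise TokenizerError(
                f"{len(self.pieces)} pieces != configured vocab_size {self.config.vocab_size}"
            )
        if any(not p for p in self.pieces):
            raise TokenizerError("empty piece in vocabulary")
        if self.pieces[: len(self.config.special_tokens)] != self.config.special_tokens:
            raise TokenizerError("special tokens must occupy the first ids")
        return self

    def model_post_init(self, __context) -> None:
        object.__setattr__(self, "_piece_to_id", {p: i for i, p in enumerate(self.pieces)})
        object.__setattr__(
            self, "_merge_rank", {tuple(m): r for r, m in enumerate(self.merges)}
        )
        object.__setattr__(self, "_piece_set", frozenset(self.pieces))

    @property
    def size(self) -> int:
        return len(self.pieces)

    def piece_id(self, piece: str) -> int:
        return self._piece_to_id[piece]

    @property
    def pad_id(self) -> int:
        return self._piece_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self._piece_to_id[UNK]

    @property
    def bos_id(self) -> int:
        return self._piece_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self._piece_to_id[EOS]

    def special_ids(self) -> set[int]:
        return set(range(len(self.config.special_tokens)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pieces": self.pieces,
                    "merges": [list(m) for m in self.merges],
                    "config": self.config.model_dump(),
                },
                ensure_ascii=False,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubwordVocabulary":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            pieces=obj["pieces"],
            merges=[tuple(m) for m in obj["merges"]],
            config=TokenizerConfig.model_validate(obj["config"]),
        )


def _words_of(sentence: str) -> list[str]:
    return unicodedata.normalize("NFC", sentence).split()


def _word_symbols(word: str) -> tuple[str, ...]:
    return tuple([WORD_BOUNDARY] + list(word))


def train_tokenizer(sentences: list[str], config: TokenizerConfig | None = None) -> SubwordVocabulary:
    """Learn a byte-pair vocabulary of exactly ``config.vocab_size`` pieces.

    Deterministic: merge candidates are ranked by corpus frequency with
    lexicographic tie-breaking.  Every character seen in training becomes a
    piece, so training text is always encodable.  Raises if the corpus cannot
    support the requested size (too few distinct merges available).
    """
    config = config or TokenizerConfig()
    if not sentences:
        raise TokenizerError("no training sentences")
    word_freq = Counter(w for s in sentences for w in _words_of(s))
    if not word_freq:
        raise TokenizerError("training sentences contain no words")

    alphabet = sorted({c for w in word_freq for c in w} | {WORD_BOUNDARY})
    pieces = list(config.special_tokens) + alphabet
    if len(pieces) >= config.vocab_size:
        raise TokenizerError(
            f"alphabet plus specials ({len(pieces)}) already reaches vocab_size "
            f"{config.vocab_size}; increase vocab_size"
        )

    symbolized: dict[tuple[str, ...], int] = {
        _word_symbols(w): f for w, f in word_freq.items()
    }
    merges: list[tuple[str, str]] = []
    existing = set(pieces)
    while len(pieces) < config.vocab_size:
        pair_freq: Counter[tuple[str, str]] = Counter()
        for syms, f in symbolized.items():
            for a, b in zip(syms, syms[1:]):
                pair_freq[(a, b)] += f
        candidates = [pair for pair in pair_freq if pair[0] + pair[1] not in existing]
        if not candidates:
            raise TokenizerError(
                f"corpus too small to support vocab_size {config.vocab_size} "
                f"(exhausted at {len(pieces)} pieces); use a smaller vocab_size"
            )
        pair = min(candidates, key=lambda p: (-pair_freq[p], p))
        merged = pair[0] + pair[1]
        merges.append(pair)
        pieces.append(merged)
        existing.add(merged)
        new_symbolized: dict[tuple[str, ...], int] = {}
        for syms, f in symbolized.items():
            out: list[str] = []
            i = 0
            while i < len(syms):
                if i + 1 < len(syms) and syms[i] == pair[0] and syms[i + 1] == pair[1]:
                    out.append(merged)
                    i += 2
                else:
                    out.append(syms[i])
                    i += 1
            new_symbolized[tuple(out)] = new_symbolized.get(tuple(out), 0) + f
        symbolized = new_symbolized
    return SubwordVocabulary(pieces=pieces, merges=merges, config=config)


def _encode_word(vocab: SubwordVocabulary, word: str) -> list[int]:
    known = vocab._piece_set
    rank = vocab._merge_rank
    syms: list[str | None] = [s if s in known else None for s in _word_symbols(word)]
    # apply merges in rank order over known-adjacent symbols
    while True:
        best_rank, best_i = None, None
        for i in range(len(syms) - 1):
            a, b = syms[i], syms[i + 1]
            if a is None or b is None:
                continue
            r = rank.get((a, b))
            if r is not None and (best_rank is None or r < best_rank):
                best_rank, best_i = r, i
        if best_i is None:
            break
        syms[best_i: best_i + 2] = [syms[best_i] + syms[best_i + 1]]
    return [vocab.unk_id if s is None else vocab.piece_id(s) for s in syms]


def encode(vocab: SubwordVocabulary, sentence: str, add_bos: bool = False,
           add_eos: bool = False) -> list[int]:
    """Encode text to token ids.  Whitespace-split words are segmented with
    the learned merges; characters unseen in training map to the unknown id.
    A word exactly equal to a special token string passes through as that
    special id (used for the report-start placeholder)."""
    specials = {t: i for i, t in enumerate(vocab.config.special_tokens)}
    ids: list[int] = []
    if add_bos:
        ids.append(vocab.bos_id)
    for word in _words_of(sentence):
        if word in specials:
            ids.append(specials[word])
        else:
            ids.extend(_encode_word(vocab, word))
    if add_eos:
        ids.append(vocab.eos_id)
    return ids


def decode(vocab: SubwordVocabulary, ids: list[int]) -> str:
    """Inverse of :func:`encode`: special tokens are stripped, word-boundary
    markers become spaces.  Raises on out-of-range ids."""
    special = vocab.special_ids()
    parts: list[str] = []
    for i in ids:
        if not 0 <= i < vocab.size:
            raise TokenizerError(f"token id {i} out of range [0, {vocab.size})")
        if i in special:
            continue
        parts.append(vocab.pieces[i])
    return "".join(parts).replace(WORD_BOUNDARY, " ").strip()
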