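"""Random sentence augmentations that virtually enlarge the training data.

Five word-level operators — synonym replacement, adjacent swap, interior
insertion, end-of-sentence addition, deletion — each applied independently
with its own probability, capped at ``max_ops_per_sentence`` operators per
sentence.  Augmentation acts on whitespace words before subword encoding, and
only ever on the *initial* (context) sentence of a training pattern: the
target sentence is the supervision signal and stays gold.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_io import REPORT_START, TrainingPattern


class AugmentationConfig(BaseModel):
    p_swap: float = 0.1
    p_delete: float = 0.1
    p_add: float = 0.1
    p_synonym: float = 0.1
    p_insert: float = 0.1
    max_ops_per_sentence: int = 2
    synonym_table: dict[str, list[str]] = Field(default_factory=dict)
    #: unigram lexicon (with optional weights) that addition/insertion sample from
    lexicon: list[str] = Field(default_factory=list)
    lexicon_weights: list[float] | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AugmentationConfig":
        for name in ("p_swap", "p_delete", "p_add", "p_synonym", "p_insert"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_ops_per_sentence < 0:
            raise ValueError("max_ops_per_sentence must be >= 0")
        if self.lexicon_weights is not None and len(self.lexicon_weights) != len(self.lexicon):
            raise ValueError("lexicon_weights length must match lexicon")
        return self

    def _lexicon_probs(self) -> np.ndarray | None:
        if not self.lexicon:
            return None
        if self.lexicon_weights is None:
            return np.full(len(self.lexicon), 1.0 / len(self.lexicon))
        w = np.asarray(self.lexicon_weights, dtype=float)
        return w / w.sum()


def _sample_word(rng: np.random.Generator, config: AugmentationConfig) -> str | None:
    probs = config._lexicon_probs()
    if probs is None:
        return None
    return config.lexicon[int(rng.choice(len(config.lexicon), p=probs))]


def augment_sentence(words: list[str], config: AugmentationConfig,
                     rng: np.random.Generator) -> list[str]:
    """Apply the operators in priority order (synonym, swap, insert, add,
    delete), each with its own probability, at most ``max_ops_per_sentence``
    in total.  Never returns an empty sequence: deletion is skipped on
    length-1 input.  Operators that cannot act (no synonym entry, empty
    lexicon) are no-ops and do not consume the budget."""
    if not words:
        raise ValueError("cannot augment an empty word sequence")
    out = list(words)
    ops_done = 0

    def budget() -> bool:
        return ops_done < config.max_ops_per_sentence

    # synonym: replace one random word that has a synonym-table entry
    if budget() and rng.random() < config.p_synonym:
        candidates = [i for i, w in enumerate(out) if config.synonym_table.get(w)]
        if candidates:
            i = int(candidates[int(rng.integers(len(candidates)))])
            syns = sorted(config.synonym_table[out[i]])
            out[i] = syns[int(rng.integers(len(syns)))]
            ops_done += 1
    # swap: exchange one random adjacent pair
    if budget() and rng.random() < config.p_swap and len(out) >= 2:
        i = int(rng.integers(len(out) - 1))
        out[i], out[i + 1] = out[i + 1], out[i]
        ops_done += 1
    # insert: new word at a random interior position
    if budget() and rng.random() < config.p_insert:
        w = _sample_word(rng, config)
        if w is not None:
            pos = int(rng.integers(1, len(out))) if len(out) > 1 else 1
            out.insert(pos, w)
            ops_done += 1
    # add: new word appended at sentence end
    if budget() and rng.random() < config.p_add:
        w = _sample_word(rng, config)
        if w is not None:
            out.append(w)
            ops_done += 1
    # delete: remove one random word, guarded against emptying the sentence
    if budget() and rng.random() < config.p_delete and len(out) >= 2:
        del out[int(rng.integers(len(out)))]
        ops_done += 1
    return out


def augment_patterns(patterns: list[TrainingPattern], config: AugmentationConfig,
                     multiplier: int) -> list[TrainingPattern]:
    """Return the original patterns plus (multiplier - 1) augmented copies of
    each.  Only the initial sentence is augmented; targets and keywords are
    untouched.  Deterministic given ``config.seed``."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if multiplier == 1:
        return list(patterns)
    rng = np.random.default_rng(config.seed)
    out = list(patterns)
    for _ in range(multiplier - 1):
        for pat in patterns:
            if pat.initial_sentence == REPORT_START:
                # the placeholder is a reserved token, not language
                out.append(pat.model_copy(deep=True))
                continue
            words = augment_sentence(pat.initial_sentence.split(), config, rng)
            out.append(
                TrainingPattern(
                    initial_sentence=" ".join(words),
                    target_sentence=pat.target_sentence,
                    keywords=list(pat.keywords),
                )
            )
    return out
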