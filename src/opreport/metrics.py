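"""Sentence and report similarity metrics: BLEU-2, unigram-recall ROUGE, the
embedding-cosine COSS, and METEOR.

All four score a generated sentence against its original in [0, 1]; identical
sentences score 1.0 for BLEU-2, ROUGE and COSS, and METEOR reaches its
maximum 1 - gamma * (1/m)^beta (its fragmentation penalty never fully
vanishes).  BLEU-2 and METEOR are sensitive to word order; ROUGE and COSS are
not.  Word-level metrics operate on whitespace-tokenized text; COSS operates
on subword token embeddings from the model's embedding table.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from pydantic import BaseModel, model_validator

from .corpus_io import Report
from .tokenizer import SubwordVocabulary, encode as sp_encode

METRIC_NAMES = ("BLEU2", "ROUGE", "COSS", "METEOR")


def _ngram_counts(words: list[str], n: int) -> Counter:
    return Counter(tuple(words[i: i + n]) for i in range(len(words) - n + 1))


def bleu2(candidate: list[str], reference: list[str]) -> float:
    """Sentence-level BLEU-2: geometric mean of unigram and bigram precisions
    (bigram precision add-one smoothed) times the brevity penalty.  Measures
    how many two-word pairs of the generated sentence match the original."""
    if not reference:
        raise ValueError("empty reference")
    if not candidate:
        return 0.0
    c, r = len(candidate), len(reference)
    ref1 = _ngram_counts(reference, 1)
    m1 = sum(min(v, ref1[k]) for k, v in _ngram_counts(candidate, 1).items())
    p1 = m1 / c
    if p1 == 0.0:
        return 0.0
    cand2, ref2 = _ngram_counts(candidate, 2), _ngram_counts(reference, 2)
    t2 = max(c - 1, 0)
    m2 = sum(min(v, ref2[k]) for k, v in cand2.items())
    p2 = (m2 + 1.0) / (t2 + 1.0)  # add-one smoothing; degenerate without it on short text
    bp = 1.0 if c >= r else float(np.exp(1.0 - r / c))
    return float(bp * np.sqrt(p1 * p2))


def rouge_recall(candidate: list[str], reference: list[str]) -> float:
    """Unigram recall (ROUGE-1 recall): the fraction of original-sentence
    words recovered in the generated sentence, with clipped counts."""
    if not reference:
        raise ValueError("empty reference")
    if not candidate:
        return 0.0
    cand = _ngram_counts(candidate, 1)
    ref = _ngram_counts(reference, 1)
    matched = sum(min(v, cand[k]) for k, v in ref.items())
    return matched / len(reference)


def coss(candidate_ids: list[int], reference_ids: list[int],
         embedding_table: np.ndarray) -> float:
    """Mean best-match cosine similarity between candidate and reference token
    embeddings.  For each candidate token the maximum cosine over reference
    tokens is taken (negatives clamped to 0), then averaged over candidate
    tokens.  1 when every candidate embedding coincides (up to positive
    scaling) with some reference embedding; 0 under mutual orthogonality."""
    if not candidate_ids or not reference_ids:
        return 0.0
    C = embedding_table[np.asarray(candidate_ids, dtype=np.int64)].astype(np.float64)
    R = embedding_table[np.asarray(reference_ids, dtype=np.int64)].astype(np.float64)
    cn = np.linalg.norm(C, axis=1, keepdims=True)
    rn = np.linalg.norm(R, axis=1, keepdims=True)
    cn[cn == 0] = 1.0
    rn[rn == 0] = 1.0
    sim = (C / cn) @ (R / rn).T
    best = np.clip(sim.max(axis=1), 0.0, 1.0)
    return float(best.mean())


def _meteor_alignment(candidate: list[str], reference: list[str]) -> tuple[int, int]:
    """Exact-match one-to-one alignment; returns (matches, chunks).

    Matches are the clipped unigram matches.  The alignment is built greedily
    left to right, preferring the reference position continuing the previous
    match (minimizing chunks); chunks are runs of consecutive positions on
    both sides."""
    capacity = Counter(reference)
    positions: dict[str, list[int]] = {}
    for j, w in enumerate(reference):
        positions.setdefault(w, []).append(j)
    used: set[int] = set()
    aligned: list[tuple[int, int]] = []
    prev_j = None
    for i, w in enumerate(candidate):
        if capacity[w] <= 0:
            continue
        free = [j for j in positions[w] if j not in used]
        if not free:
            continue
        if prev_j is not None and prev_j + 1 in free:
            j = prev_j + 1
        else:
            j = free[0]
        used.add(j)
        capacity[w] -= 1
        aligned.append((i, j))
        prev_j = j
    if not aligned:
        return 0, 0
    chunks = 1
    for (i0, j0), (i1, j1) in zip(aligned, aligned[1:]):
        if not (i1 == i0 + 1 and j1 == j0 + 1):
            chunks += 1
    return len(aligned), chunks


def meteor(candidate: list[str], reference: list[str], alpha: float = 0.9,
           beta: float = 3.0, gamma: float = 0.5) -> float:
    """METEOR with exact surface matching (no stemming or synonymy):
    harmonic-mean F weighted toward recall (alpha), discounted by the
    fragmentation penalty gamma * (chunks / matches) ** beta."""
    if not reference:
        raise ValueError("empty reference")
    if not candidate:
        return 0.0
    matches, chunks = _meteor_alignment(candidate, reference)
    if matches == 0:
        return 0.0
    precision = matches / len(candidate)
    recall = matches / len(reference)
    f = precision * recall / (alpha * precision + (1.0 - alpha) * recall)
    penalty = gamma * (chunks / matches) ** beta
    return float(f * (1.0 - penalty))


class MetricReport(BaseModel):
    """Per-sentence scores and their report-level means for all four metrics."""

    sentence_scores: list[dict[str, float]]
    report_scores: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "MetricReport":
        for scores in self.sentence_scores + [self.report_scores]:
            for name, v in scores.items():
                if not -1e-9 <= v <= 1.0 + 1e-9:
                    raise ValueError(f"{name} score {v} outside [0, 1]")
        return self


def score_sentence_pair(generated: str, original: str, vocab: SubwordVocabulary,
                        embedding_table: np.ndarray) -> dict[str, float]:
    cand_words, ref_words = generated.split(), original.split()
    cand_ids = sp_encode(vocab, generated)
    ref_ids = sp_encode(vocab, original)
    return {
        "BLEU2": bleu2(cand_words, ref_words),
        "ROUGE": rouge_recall(cand_words, ref_words),
        "COSS": coss(cand_ids, ref_ids, embedding_table),
        "METEOR": meteor(cand_words, ref_words),
    }


def score_report(generated: Report, original: Report, vocab: SubwordVocabulary,
                 embedding_table: np.ndarray) -> MetricReport:
    """Score a generated report against its original, sentence i against
    sentence i (alignment is positional); report scores are arithmetic means
    of the sentence scores."""
    if len(generated.sentences) != len(original.sentences):
        raise ValueError(
            f"sentence count mismatch: generated {len(generated.sentences)} "
            f"vs original {len(original.sentences)}"
        )
    sentence_scores = [
        score_sentence_pair(g.text, o.text, vocab, embedding_table)
        for g, o in zip(generated.sentences, original.sentences)
    ]
    report_scores = {
        name: float(np.mean([s[name] for s in sentence_scores])) for name in METRIC_NAMES
    }
    return MetricReport(sentence_scores=sentence_scores, report_scores=report_scores)
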