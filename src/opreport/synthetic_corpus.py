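"""Seeded generator of annotated report corpora with a learnable keyword grammar.

The real training data (48 operation reports of functional endoscopic sinus
surgery) is private, so this module produces corpora with the same statistics:
48 reports of 10-45 sentences (~1500 sentences total, ~8 words each), a
150-keyword vocabulary and 2-4 keywords per sentence.  Sentences are written
in a pseudo-German language of invented word forms.  Crucially the mapping
keyword-set -> sentence is deterministic up to synonym choice and filler
noise, so a correctly implemented sequence model can actually learn it; the
noise keeps the metrics away from a saturated 1.0 before any training.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_io import AnnotatedCorpus, Report, Sentence

_ONSETS = [
    "b", "br", "d", "f", "g", "gr", "h", "k", "kl", "kn", "l", "m", "n", "p",
    "pf", "r", "s", "sch", "schl", "sp", "st", "t", "tr", "v", "w", "z",
]
_NUCLEI = ["a", "e", "i", "o", "u", "au", "ei", "ie", "eu", "oe", "ue", "aa"]
_CODAS = ["", "ch", "ck", "l", "m", "n", "nd", "ng", "r", "rt", "s", "st", "tz"]


class ConfigError(ValueError):
    """Raised for invalid or infeasible generator configurations."""


class SyntheticCorpusConfig(BaseModel):
    n_reports: int = 48
    sentences_per_report_range: tuple[int, int] = (10, 45)
    target_total_sentences: int = 1500
    mean_words_per_sentence: int = 8
    n_keywords: int = 150
    keywords_per_sentence_range: tuple[int, int] = (2, 4)
    synonym_set_size: int = 3
    noise_word_rate: float = 0.15
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCorpusConfig":
        for name in ("n_reports", "target_total_sentences", "mean_words_per_sentence",
                     "n_keywords", "synonym_set_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("sentences_per_report_range", "keywords_per_sentence_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be a non-empty positive interval")
        if not 0.0 <= self.noise_word_rate < 1.0:
            raise ConfigError("noise_word_rate must lie in [0, 1)")
        if self.n_reports * self.sentences_per_report_range[0] > 1.1 * self.target_total_sentences:
            raise ConfigError(
                "infeasible: n_reports x min sentences per report exceeds "
                "110% of target_total_sentences"
            )
        if self.n_reports * self.sentences_per_report_range[1] < 0.9 * self.target_total_sentences:
            raise ConfigError(
                "infeasible: n_reports x max sentences per report cannot reach "
                "90% of target_total_sentences"
            )
        return self


class KeywordGrammar(BaseModel):
    """Keyword -> phrase templates.  A template is a list of slots; each slot
    is a list of interchangeable surface words (length 1 = fixed word, longer
    = synonym slot).  Stands in for the surgeons' actual phrasing."""

    keyword_templates: dict[str, list[list[list[str]]]]
    filler_words: list[str]

    @model_validator(mode="after")
    def _check(self) -> "KeywordGrammar":
        for kw, templates in self.keyword_templates.items():
            if not templates:
                raise ConfigError(f"keyword {kw!r} has no templates")
        return self

    def synonym_table(self) -> dict[str, set[str]]:
        """Word -> interchangeable words, harvested from the synonym slots
        (usable as the augmentation synonym table)."""
        table: dict[str, set[str]] = {}
        for templates in self.keyword_templates.values():
            for template in templates:
                for slot in template:
                    if len(slot) > 1:
                        for w in slot:
                            table.setdefault(w, set()).update(x for x in slot if x != w)
        return table


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for _ in range(n_syllables):
        parts.append(_ONSETS[rng.integers(len(_ONSETS))])
        parts.append(_NUCLEI[rng.integers(len(_NUCLEI))])
        parts.append(_CODAS[rng.integers(len(_CODAS))])
    return "".join(parts)


def _make_lexicon(rng: np.random.Generator, n: int, syllables: tuple[int, ...],
                  taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        w = _make_word(rng, int(rng.choice(syllables)))
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def generate_grammar(config: SyntheticCorpusConfig) -> KeywordGrammar:
    """Build a deterministic keyword grammar: exactly ``config.n_keywords``
    keywords, each with one 2- or 3-word template containing the keyword
    surface itself plus companion words, one slot being a synonym set."""
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    keywords = _make_lexicon(rng, config.n_keywords, (2, 3), taken)
    n_content = max(2 * config.n_keywords, 60)
    content = _make_lexicon(rng, n_content, (1, 2, 3), taken)
    fillers = _make_lexicon(rng, 14, (1,), taken)

    templates: dict[str, list[list[list[str]]]] = {}
    for kw in keywords:
        companion_ids = rng.choice(n_content, size=config.synonym_set_size, replace=False)
        synonym_slot = sorted(content[i] for i in companion_ids)
        template: list[list[str]] = [[kw], synonym_slot]
        if rng.random() < 0.4:  # some keywords carry a third, fixed word
            template.append([content[int(rng.integers(n_content))]])
        templates[kw] = [template]
    return KeywordGrammar(keyword_templates=templates, filler_words=fillers)


def _report_sentence_counts(rng: np.random.Generator, config: SyntheticCorpusConfig) -> list[int]:
    """Sample per-report sentence counts in range, then nudge the total toward
    the target (exactness is not forced; +-10% is accepted)."""
    lo, hi = config.sentences_per_report_range
    counts = rng.integers(lo, hi + 1, size=config.n_reports).astype(int)
    target = config.target_total_sentences
    scale = target / counts.sum()
    counts = np.clip(np.rint(counts * scale).astype(int), lo, hi)
    # distribute any residual one sentence at a time, respecting the range
    order = rng.permutation(config.n_reports)
    guard = 0
    while counts.sum() != target and guard < 10 * config.n_reports:
        for i in order:
            diff = target - counts.sum()
            if diff == 0:
                break
            if diff > 0 and counts[i] < hi:
                counts[i] += 1
            elif diff < 0 and counts[i] > lo:
                counts[i] -= 1
        guard += 1
    total = counts.sum()
    if abs(total - target) > 0.1 * target:
        raise ConfigError(
            f"could not reconcile sentence counts: total {total} vs target {target}"
        )
    return [int(c) for c in counts]


def _realize_sentence(rng: np.random.Generator, keywords: list[str],
                      grammar: KeywordGrammar, noise_rate: float) -> str:
    words: list[str] = []
    for kw in sorted(keywords):  # canonical order keeps the mapping learnable
        templates = grammar.keyword_templates[kw]
        template = templates[int(rng.integers(len(templates)))]
        for slot in template:
            words.append(slot[int(rng.integers(len(slot)))])
    out: list[str] = []
    for w in words:
        if rng.random() < noise_rate:
            out.append(grammar.filler_words[int(rng.integers(len(grammar.filler_words)))])
        out.append(w)
    if rng.random() < noise_rate:
        out.append(grammar.filler_words[int(rng.integers(len(grammar.filler_words)))])
    return " ".join(out)


def generate_corpus(config: SyntheticCorpusConfig, grammar: KeywordGrammar) -> AnnotatedCorpus:
    """Generate an annotated corpus from the grammar, deterministic given the
    config seed.  Keywords per sentence are drawn uniformly from the
    configured range; the declared keyword vocabulary is the grammar's."""
    keywords = sorted(grammar.keyword_templates)
    if len(keywords) != config.n_keywords:
        raise ConfigError(
            f"grammar has {len(keywords)} keywords, config expects {config.n_keywords}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    counts = _report_sentence_counts(rng, config)
    lo_k, hi_k = config.keywords_per_sentence_range
    reports: list[Report] = []
    for r, n_sent in enumerate(counts):
        sentences: list[Sentence] = []
        for _ in range(n_sent):
            k = int(rng.integers(lo_k, hi_k + 1))
            kws = [keywords[i] for i in rng.choice(len(keywords), size=k, replace=False)]
            text = _realize_sentence(rng, kws, grammar, config.noise_word_rate)
            sentences.append(Sentence(text=text, keywords=kws))
        reports.append(Report(report_id=f"report-{r:03d}", sentences=sentences))
    return AnnotatedCorpus(reports=reports, keyword_vocabulary=set(keywords))


class CorpusStatistics(BaseModel):
    n_reports: int
    n_sentences: int
    mean_words_per_sentence: float
    min_words_per_sentence: int
    max_words_per_sentence: int
    keyword_vocabulary_size: int
    keywords_per_sentence_histogram: dict[int, int] = Field(default_factory=dict)


def corpus_statistics(corpus: AnnotatedCorpus) -> CorpusStatistics:
    """Summary statistics of a corpus (errors on an empty corpus)."""
    sentences = corpus.all_sentences()
    if not sentences:
        raise ConfigError("empty corpus: no statistics to compute")
    lengths = [len(s.words()) for s in sentences]
    hist: dict[int, int] = {}
    for s in sentences:
        hist[len(s.keywords)] = hist.get(len(s.keywords), 0) + 1
    return CorpusStatistics(
        n_reports=len(corpus.reports),
        n_sentences=len(sentences),
        mean_words_per_sentence=float(np.mean(lengths)),
        min_words_per_sentence=int(min(lengths)),
        max_words_per_sentence=int(max(lengths)),
        keyword_vocabulary_size=len(corpus.keyword_vocabulary),
        keywords_per_sentence_histogram=dict(sorted(hist.items())),
    )
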