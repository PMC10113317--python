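"""Annotated operation-report corpora: domain types, JSONL I/O, training patterns.

A corpus is a list of reports; each report is an ordered list of sentences;
each sentence carries the 2-4 dictated keywords (anchor words) it was written
from.  Consecutive sentences of a report are paired into supervised training
patterns (initial sentence, target sentence, keywords of the target), the unit
the language model is trained on.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

from pydantic import BaseModel, Field, field_validator, model_validator

#: Placeholder standing in for the (nonexistent) sentence preceding a report's
#: first sentence, so that every sentence yields a training pattern.
REPORT_START = "<START_REPORT>"

#: Corpus-conformance bounds (validator flags, not hard failures).
KEYWORDS_PER_SENTENCE = (2, 4)
SENTENCES_PER_REPORT = (10, 45)


class CorpusFormatError(ValueError):
    """Raised for unreadable or structurally invalid corpus files."""


class CorpusValidationError(ValueError):
    """Raised when corpus content violates a hard invariant."""


class Sentence(BaseModel):
    text: str
    keywords: list[str] = Field(default_factory=list)

    @field_validator("text")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("sentence text empty after whitespace trimming")
        return v.strip()

    def words(self) -> list[str]:
        return self.text.split()


class Report(BaseModel):
    report_id: str
    sentences: list[Sentence] = Field(default_factory=list)


class ValidationSummary(BaseModel):
    """Conformance report: real dictation may violate the corpus statistics,
    so violations are collected rather than rejected."""

    n_reports: int = 0
    n_sentences: int = 0
    issues: list[str] = Field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.issues)

    @property
    def conformant(self) -> bool:
        return not self.issues


class AnnotatedCorpus(BaseModel):
    reports: list[Report] = Field(default_factory=list)
    keyword_vocabulary: set[str] = Field(default_factory=set)

    @model_validator(mode="after")
    def _check_invariants(self) -> "AnnotatedCorpus":
        seen: set[str] = set()
        for rep in self.reports:
            if rep.report_id in seen:
                raise CorpusValidationError(f"duplicate report_id {rep.report_id!r}")
            seen.add(rep.report_id)
            for sent in rep.sentences:
                missing = set(sent.keywords) - self.keyword_vocabulary
                if missing:
                    raise CorpusValidationError(
                        f"report {rep.report_id!r}: keywords {sorted(missing)} "
                        "not in keyword_vocabulary"
                    )
        return self

    def all_sentences(self) -> list[Sentence]:
        return [s for r in self.reports for s in r.sentences]


class TrainingPattern(BaseModel):
    """Supervised triple: the previous sentence (context), the sentence to
    generate, and the keywords the target sentence was annotated with."""

    initial_sentence: str
    target_sentence: str
    keywords: list[str]


def validate_conformance(corpus: AnnotatedCorpus) -> ValidationSummary:
    """Flag departures from the expected corpus statistics (2-4 keywords per
    sentence, 10-45 sentences per report) without rejecting the corpus."""
    lo_k, hi_k = KEYWORDS_PER_SENTENCE
    lo_s, hi_s = SENTENCES_PER_REPORT
    issues: list[str] = []
    n_sent = 0
    for rep in corpus.reports:
        n = len(rep.sentences)
        n_sent += n
        if not lo_s <= n <= hi_s:
            issues.append(f"report {rep.report_id!r}: {n} sentences outside [{lo_s}, {hi_s}]")
        for i, sent in enumerate(rep.sentences):
            k = len(sent.keywords)
            if not lo_k <= k <= hi_k:
                issues.append(
                    f"report {rep.report_id!r} sentence {i}: {k} keywords outside [{lo_k}, {hi_k}]"
                )
    return ValidationSummary(n_reports=len(corpus.reports), n_sentences=n_sent, issues=issues)


def load_corpus(path: str | Path) -> AnnotatedCorpus:
    """Read a JSONL corpus (one report object per line).

    The keyword vocabulary is the union of all sentence keywords.  A
    conformance summary is attached as ``corpus.validation`` (violations are
    collected, not dropped).  Raises :class:`FileNotFoundError`,
    :class:`CorpusFormatError` (empty file, malformed line — the message names
    the line number) or :class:`CorpusValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reports: list[Report] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                reports.append(Report.model_validate(obj))
            except (json.JSONDecodeError, ValueError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed report line: {exc}") from exc
    if not reports:
        raise CorpusFormatError(f"{path}: empty corpus (no report lines)")
    vocab = {kw for rep in reports for s in rep.sentences for kw in s.keywords}
    corpus = AnnotatedCorpus(reports=reports, keyword_vocabulary=vocab)
    # attached out-of-band: the summary is diagnostic, not part of the data model
    object.__setattr__(corpus, "validation", validate_conformance(corpus))
    return corpus


def write_corpus(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Write the corpus in the JSONL format read by :func:`load_corpus`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rep in corpus.reports:
            fh.write(json.dumps(rep.model_dump(), ensure_ascii=False) + "\n")


def export_text(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Human-readable export: one sentence per line, blank line between reports."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for i, rep in enumerate(corpus.reports):
            if i:
                fh.write("\n")
            for sent in rep.sentences:
                fh.write(sent.text + "\n")


def build_training_patterns(
    corpus: AnnotatedCorpus, skip_first: bool = False
) -> list[TrainingPattern]:
    """Pair consecutive sentences of each report into training patterns.

    A report with n sentences yields n patterns: sentence i is the target with
    sentence i-1 as initial sentence; the first sentence uses the
    ``REPORT_START`` placeholder.  With ``skip_first=True`` the placeholder
    patterns are omitted (n-1 patterns per report).  No pattern crosses a
    report boundary.
    """
    if not corpus.reports:
        raise CorpusValidationError("empty corpus: no reports to build patterns from")
    patterns: list[TrainingPattern] = []
    for rep in corpus.reports:
        if not rep.sentences:
            warnings.warn(f"report {rep.report_id!r} has no sentences; skipped")
            continue
        prev = REPORT_START
        for i, sent in enumerate(rep.sentences):
            if not (skip_first and i == 0):
                patterns.append(
                    TrainingPattern(
                        initial_sentence=prev,
                        target_sentence=sent.text,
                        keywords=list(sent.keywords),
                    )
                )
            prev = sent.text
    return patterns


def keyword_groups(report: Report) -> list[list[str]]:
    """The dictation view of a report: the ordered per-sentence keyword lists."""
    return [list(s.keywords) for s in report.sentences]
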