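"""Before/after evaluation of the language model.

Every report is disassembled into its per-sentence keyword groups and
regenerated twice: once with the seed-initialized *untrained* model (the
"before training" arm) and once with the trained model of the
cross-validation fold that held the report out (the "after training" arm).
Both generations are scored against the original report with all four
metrics; the paired per-report scores are compared with the Wilcoxon
signed-rank test (tie-corrected normal approximation, SPSS sign convention:
negative Z when the after-arm ranks higher).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .corpus_io import AnnotatedCorpus, keyword_groups
from .metrics import METRIC_NAMES, score_report
from .model import ModelConfig, generate_report, init_model
from .tokenizer import SubwordVocabulary
from .training import FoldResult, TrainingConfig, run_cross_validation


class DegenerateDataError(ValueError):
    pass


class PairedScores(BaseModel):
    """Per-report before/after scores for each metric, aligned by position."""

    report_ids: list[str]
    before: dict[str, list[float]]
    after: dict[str, list[float]]

    @model_validator(mode="after")
    def _check(self) -> "PairedScores":
        n = len(self.report_ids)
        for name in METRIC_NAMES:
            if len(self.before.get(name, [])) != n or len(self.after.get(name, [])) != n:
                raise ValueError(f"before/after arrays for {name} must have length {n}")
            for v in self.before[name] + self.after[name]:
                if not -1e-9 <= v <= 1 + 1e-9:
                    raise ValueError(f"{name} score {v} outside [0, 1]")
        return self

    @property
    def n(self) -> int:
        return len(self.report_ids)


class WilcoxonResult(BaseModel):
    metric: str = ""
    z: float
    p: float
    w: float
    n_effective: int
    small_sample: bool = False  # normal approximation shaky below 5 pairs


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic programming
    over the null distribution of the rank sum (all sign assignments equally
    likely).  Mid-ranks are doubled so tied ranks stay integral."""
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in r2:
        top += int(r)
        counts[int(r): top + 1] += counts[: top + 1 - int(r)]
    counts /= counts.sum()
    mu = total / 2.0
    dev = abs(2 * w_obs - mu)
    support = np.arange(total + 1, dtype=np.float64)
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(before: list[float], after: list[float],
                         continuity: bool = False,
                         method: str = "approx") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are excluded; absolute differences are mid-ranked; W is
    the sum of ranks of the negative differences (after - before < 0), so
    uniform improvement gives W = 0 and a *negative* Z.  Two-sided p.

    ``method="approx"`` (default) reports the tie-corrected normal
    approximation without continuity correction, matching what statistics
    packages print for large samples.  ``method="exact"`` replaces the
    p-value with the exact null distribution of the rank sum, the reliable
    choice for small samples where the normal approximation can be off by
    several hundredths; the Z statistic is reported either way.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("degenerate: no nonzero before/after differences")
    ranks = stats.rankdata(np.abs(d))
    w_neg = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateDataError("degenerate: zero variance (all differences tied at one rank)")
    num = w_neg - mu
    if continuity:
        num -= 0.5 * np.sign(num)
    z = float(num / np.sqrt(var))
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_neg)
    elif method == "approx":
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(z=z, p=p, w=w_neg, n_effective=int(n), small_sample=n < 5)


def before_after_experiment(corpus: AnnotatedCorpus, vocab: SubwordVocabulary,
                            model_config: ModelConfig, training_config: TrainingConfig,
                            seed: int | None = None,
                            cv_results: list[FoldResult] | None = None,
                            unit: str = "report") -> PairedScores:
    """Generate and score every report with the untrained and the out-of-fold
    trained model.  COSS uses each arm's own embedding table (the metric is
    defined on the model's embedding layer).  Deterministic given the seed.

    ``cv_results`` may carry pre-trained fold models to reuse; otherwise the
    cross-validation is run here.  The paired unit is the report
    (``unit="report"``, the default); ``unit="sentence"`` pairs individual
    sentences instead.
    """
    if unit not in ("report", "sentence"):
        raise ValueError(f"unknown pairing unit {unit!r}")
    master = training_config.seed if seed is None else seed
    untrained = init_model(model_config, seed=master)
    if cv_results is None:
        cv_results = run_cross_validation(corpus, vocab, model_config,
                                          training_config, seed=master)
    fold_of = {rid: res for res in cv_results for rid in res.held_out_report_ids}
    report_ids: list[str] = []
    before = {name: [] for name in METRIC_NAMES}
    after = {name: [] for name in METRIC_NAMES}
    for report in corpus.reports:
        groups = keyword_groups(report)
        gen_before = generate_report(untrained, vocab, groups)
        trained = fold_of[report.report_id].params
        gen_after = generate_report(trained, vocab, groups)
        scores_b = score_report(gen_before, report, vocab, untrained.embedding_table)
        scores_a = score_report(gen_after, report, vocab, trained.embedding_table)
        if unit == "report":
            report_ids.append(report.report_id)
            for name in METRIC_NAMES:
                before[name].append(scores_b.report_scores[name])
                after[name].append(scores_a.report_scores[name])
        else:
            for i, (sb, sa) in enumerate(zip(scores_b.sentence_scores,
                                             scores_a.sentence_scores)):
                report_ids.append(f"{report.report_id}#{i}")
                for name in METRIC_NAMES:
                    before[name].append(sb[name])
                    after[name].append(sa[name])
    return PairedScores(report_ids=report_ids, before=before, after=after)


class MetricSummary(BaseModel):
    metric: str
    mean_before: float
    mean_after: float
    z: float
    p: float
    n_effective: int
    improved: bool


class ExperimentSummary(BaseModel):
    n_reports: int
    metrics: list[MetricSummary] = Field(default_factory=list)

    def by_metric(self) -> dict[str, MetricSummary]:
        return {m.metric: m for m in self.metrics}

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


def experiment_report(paired: PairedScores, significance: float = 0.001
                      ) -> ExperimentSummary:
    """Summarize the paired scores: per metric the before/after means, the
    Wilcoxon Z and p, and whether training improved the metric (mean after >
    mean before at p below the significance level)."""
    if paired.n < 5:
        raise DegenerateDataError("need at least 5 paired reports")
    summary = ExperimentSummary(n_reports=paired.n)
    for name in METRIC_NAMES:
        res = wilcoxon_signed_rank(paired.before[name], paired.after[name])
        mb = float(np.mean(paired.before[name]))
        ma = float(np.mean(paired.after[name]))
        summary.metrics.append(MetricSummary(
            metric=name, mean_before=mb, mean_after=ma, z=res.z, p=res.p,
            n_effective=res.n_effective,
            improved=bool(ma > mb and res.p < significance),
        ))
    return summary


def write_experiment_outputs(paired: PairedScores, summary: ExperimentSummary,
                             out_dir: str | Path) -> None:
    """results/: paired_scores.csv, wilcoxon.json, summary.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "paired_scores.csv").open("w", encoding="utf-8") as fh:
        fh.write("report_id,metric,before,after\n")
        for i, rid in enumerate(paired.report_ids):
            for name in METRIC_NAMES:
                fh.write(f"{rid},{name},{paired.before[name][i]:.6f},"
                         f"{paired.after[name][i]:.6f}\n")
    (out / "wilcoxon.json").write_text(summary.to_json(), encoding="utf-8")
    lines = [
        "# Before/after training evaluation",
        "",
        f"{summary.n_reports} reports, paired Wilcoxon signed-rank test.",
        "",
        "| metric | mean before | mean after | Z | p | improved |",
        "|---|---|---|---|---|---|",
    ]
    for m in summary.metrics:
        lines.append(
            f"| {m.metric} | {m.mean_before:.4f} | {m.mean_after:.4f} "
            f"| {m.z:.3f} | {m.p:.2e} | {'yes' if m.improved else 'no'} |"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
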