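"""k-fold training pipeline: report-level folds, 85:15 pattern split,
augmentation, teacher-forced optimization with Adam.

Folds partition *reports* (never sentences of one report), so no fold's
training data leaks held-out report content.  Within the left-in reports,
patterns are shuffled and split 85:15 into training and validation; only the
training side is augmented.  Held-out reports supply the "after training"
generation set of the before/after experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .augmentation import AugmentationConfig, augment_patterns
from .corpus_io import AnnotatedCorpus, TrainingPattern, build_training_patterns
from .model import (
    ModelConfig,
    ModelParams,
    assemble_pattern_input,
    check_vocab_compatible,
    init_model,
    loss_and_grads,
)
from .tokenizer import SubwordVocabulary, encode as sp_encode


class TrainingError(RuntimeError):
    pass


class TrainingConfig(BaseModel):
    k: int = 10
    split_ratio: float = 0.85
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-2
    clip_norm: float = 1.0
    early_stopping_patience: int = 5
    aug: AugmentationConfig | None = None
    aug_multiplier: int = 1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrainingConfig":
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.aug_multiplier < 1:
            raise ValueError("aug_multiplier must be >= 1")
        return self


class FoldPlan(BaseModel):
    assignments: dict[str, int]
    k: int

    @model_validator(mode="after")
    def _check(self) -> "FoldPlan":
        folds = set(self.assignments.values())
        if folds and (min(folds) < 0 or max(folds) >= self.k):
            raise ValueError("fold index out of range")
        sizes = self.fold_sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")
        return self

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes

    def held_out(self, fold: int) -> list[str]:
        return sorted(r for r, f in self.assignments.items() if f == fold)

    def left_in(self, fold: int) -> list[str]:
        return sorted(r for r, f in self.assignments.items() if f != fold)


def make_folds(corpus: AnnotatedCorpus, k: int, seed: int) -> FoldPlan:
    """Balanced random partition of reports into k folds (sizes differ by at
    most one), deterministic given the seed."""
    ids = [r.report_id for r in corpus.reports]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds report count {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[int(j)]: i % k for i, j in enumerate(order)}
    return FoldPlan(assignments=assignments, k=k)


def split_patterns(patterns: list[TrainingPattern], ratio: float, seed: int
                   ) -> tuple[list[TrainingPattern], list[TrainingPattern]]:
    """Shuffle and split patterns into disjoint, exhaustive train/validation
    sets; neither side is left empty."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patterns))
    n_train = int(round(ratio * len(patterns)))
    n_train = min(max(n_train, 1), len(patterns) - 1)
    train = [patterns[int(i)] for i in order[:n_train]]
    val = [patterns[int(i)] for i in order[n_train:]]
    return train, val


def encode_patterns(patterns: list[TrainingPattern], vocab: SubwordVocabulary
                    ) -> list[tuple[list[int], list[int]]]:
    """Numeric form of patterns: (input ids, target ids incl. <eos>)."""
    out = []
    for pat in patterns:
        x = assemble_pattern_input(vocab, pat.keywords, pat.initial_sentence)
        y = sp_encode(vocab, pat.target_sentence, add_eos=True)
        out.append((x, y))
    return out


def _pad_batch(encoded: list[tuple[list[int], list[int]]], bos_id: int, pad_id: int):
    B = len(encoded)
    Tx = max(len(x) for x, _ in encoded)
    Ty = max(len(y) for _, y in encoded)
    X = np.full((B, Tx), pad_id, dtype=np.int64)
    Mx = np.zeros((B, Tx))
    Yin = np.full((B, Ty), pad_id, dtype=np.int64)
    Yout = np.full((B, Ty), pad_id, dtype=np.int64)
    My = np.zeros((B, Ty))
    for b, (x, y) in enumerate(encoded):
        X[b, : len(x)] = x
        Mx[b, : len(x)] = 1.0
        Yin[b, 0] = bos_id
        Yin[b, 1: len(y)] = y[:-1]
        Yout[b, : len(y)] = y
        My[b, : len(y)] = 1.0
    return X, Mx, Yin, Yout, My


class _Adam:
    def __init__(self, arrays: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            arrays[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _mean_loss(params: ModelParams, encoded, vocab: SubwordVocabulary,
               batch_size: int) -> float:
    """Evaluation loss: token-NLL over the set, no augmentation, no tricks."""
    total, n = 0.0, 0
    for i in range(0, len(encoded), batch_size):
        batch = encoded[i: i + batch_size]
        X, Mx, Yin, Yout, My = _pad_batch(batch, vocab.bos_id, vocab.pad_id)
        loss, _ = loss_and_grads(params, X, Mx, Yin, Yout, My, want_grads=False)
        k = int(My.sum())
        total += loss * k
        n += k
    return total / max(n, 1)


class TrainingHistory(BaseModel):
    train_loss: list[float] = Field(default_factory=list)
    val_loss: list[float] = Field(default_factory=list)
    initial_train_loss: float | None = None
    stopped_epoch: int | None = None


def train_model(params: ModelParams, train_patterns: list[TrainingPattern],
                val_patterns: list[TrainingPattern], vocab: SubwordVocabulary,
                config: TrainingConfig) -> tuple[ModelParams, TrainingHistory]:
    """Teacher-forced NLL minimization with Adam, gradient-norm clipping and
    early stopping on validation loss.  Deterministic given config.seed
    (batch order reshuffled each epoch with an epoch-derived seed).
    Returns a copy of the parameters; with epochs=0 that copy is identical
    to the input."""
    if not train_patterns:
        raise TrainingError("empty training set")
    check_vocab_compatible(params.config, vocab)
    params = params.copy()
    if config.aug is not None and config.aug_multiplier > 1:
        train_patterns = augment_patterns(train_patterns, config.aug, config.aug_multiplier)
    enc_train = encode_patterns(train_patterns, vocab)
    enc_val = encode_patterns(val_patterns, vocab) if val_patterns else []
    history = TrainingHistory()
    history.initial_train_loss = _mean_loss(params, enc_train, vocab, config.batch_size)
    if config.epochs == 0:
        return params, history

    opt = _Adam(params.arrays, config.learning_rate)
    best_val = np.inf
    best_params = params.copy()
    patience_left = config.early_stopping_patience
    # length-bucketed order reduces padding waste; reshuffled every epoch
    for epoch in range(config.epochs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, epoch]))
        order = rng.permutation(len(enc_train))
        order = sorted(order, key=lambda i: (len(enc_train[int(i)][0]) // 4, rng.random()))
        epoch_total, epoch_n = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [enc_train[int(j)] for j in order[i: i + config.batch_size]]
            X, Mx, Yin, Yout, My = _pad_batch(batch, vocab.bos_id, vocab.pad_id)
            loss, grads = loss_and_grads(params, X, Mx, Yin, Yout, My)
            if not np.isfinite(loss):
                raise TrainingError(
                    "non-finite training loss; try a smaller learning_rate"
                )
            _clip_grads(grads, config.clip_norm)
            opt.step(params.arrays, grads)
            k = int(My.sum())
            epoch_total += loss * k
            epoch_n += k
        history.train_loss.append(epoch_total / max(epoch_n, 1))
        if enc_val:
            vloss = _mean_loss(params, enc_val, vocab, config.batch_size)
            history.val_loss.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = params.copy()
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    history.stopped_epoch = epoch
                    return best_params, history
    if enc_val and np.isfinite(best_val):
        return best_params, history
    return params, history


@dataclass
class FoldResult:
    fold: int
    held_out_report_ids: list[str]
    params: ModelParams
    history: TrainingHistory


def run_cross_validation(corpus: AnnotatedCorpus, vocab: SubwordVocabulary,
                         model_config: ModelConfig, config: TrainingConfig,
                         seed: int | None = None) -> list[FoldResult]:
    """Train one model per fold on the left-in reports' (augmented) patterns;
    each report is held out exactly once.  Per-fold seeds derive
    deterministically from the master seed."""
    master = config.seed if seed is None else seed
    plan = make_folds(corpus, config.k, master)
    by_id = {r.report_id: r for r in corpus.reports}
    results: list[FoldResult] = []
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                  np.random.SeedSequence(master).spawn(config.k)]
    for fold in range(config.k):
        left_in = AnnotatedCorpus(
            reports=[by_id[i] for i in plan.left_in(fold)],
            keyword_vocabulary=corpus.keyword_vocabulary,
        )
        patterns = build_training_patterns(left_in)
        fold_cfg = config.model_copy(update={"seed": fold_seeds[fold]})
        train, val = split_patterns(patterns, config.split_ratio, fold_seeds[fold])
        params0 = init_model(model_config, seed=fold_seeds[fold])
        params, history = train_model(params0, train, val, vocab, fold_cfg)
        results.append(FoldResult(
            fold=fold,
            held_out_report_ids=plan.held_out(fold),
            params=params,
            history=history,
        ))
    return results
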