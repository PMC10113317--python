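"""Metric unit and oracle tests.

The brute-force n-gram oracle below recounts unigram/bigram matches with
naive nested loops, independent of the Counter-based implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import opreport as op
from opreport.corpus_io import Report, Sentence
from opreport.metrics import bleu2, coss, meteor, rouge_recall, score_report


# --- independent oracle: naive nested-loop n-gram counting ---------------

def _clipped_matches_bruteforce(cand, ref, n):
    cand_ngrams = [tuple(cand[i: i + n]) for i in range(len(cand) - n + 1)]
    ref_ngrams = [tuple(ref[i: i + n]) for i in range(len(ref) - n + 1)]
    used = [False] * len(ref_ngrams)
    matches = 0
    for g in cand_ngrams:
        for j, r in enumerate(ref_ngrams):
            if not used[j] and r == g:
                used[j] = True
                matches += 1
                break
    return matches, len(cand_ngrams), len(ref_ngrams)


def bleu2_oracle(cand, ref):
    if not cand:
        return 0.0
    m1, c1, _ = _clipped_matches_bruteforce(cand, ref, 1)
    p1 = m1 / c1
    if p1 == 0:
        return 0.0
    m2, c2, _ = _clipped_matches_bruteforce(cand, ref, 2)
    p2 = (m2 + 1) / (c2 + 1)
    bp = 1.0 if len(cand) >= len(ref) else np.exp(1 - len(ref) / len(cand))
    return bp * np.sqrt(p1 * p2)


def rouge_oracle(cand, ref):
    if not cand:
        return 0.0
    m, _, t = _clipped_matches_bruteforce(ref, cand, 1)  # recall: match ref into cand
    return m / len(ref)


def _random_pair(rng):
    lexicon = ["nase", "septum", "mukosa", "links", "rechts", "eroeffnet",
               "dargestellt", "blutung", "sauger", "zeigt"]
    n1, n2 = rng.integers(1, 12, size=2)
    cand = [lexicon[i] for i in rng.integers(0, len(lexicon), size=n1)]
    ref = [lexicon[i] for i in rng.integers(0, len(lexicon), size=n2)]
    return cand, ref


class TestBleu2:
    def test_identical_sentences_score_one(self):
        s = "die nase wird eroeffnet".split()
        assert bleu2(s, s) == pytest.approx(1.0)

    def test_disjoint_vocabulary_scores_zero(self):
        assert bleu2(["a", "b"], ["c", "d"]) == 0.0

    def test_hand_counted_example(self):
        # cand "a b c d" vs ref "a b x d": p1=3/4; bigrams {ab,bc,cd} vs
        # {ab,bx,xd}: m2=1, smoothed p2=(1+1)/(3+1)=1/2; no brevity penalty
        val = bleu2("a b c d".split(), "a b x d".split())
        assert val == pytest.approx(np.sqrt(0.75 * 0.5))

    def test_brevity_penalty_applied(self):
        # cand shorter than ref: BP = exp(1 - 4/2), p1=1, p2=(1+1)/(1+1)=1
        val = bleu2("a b".split(), "a b c d".split())
        assert val == pytest.approx(np.exp(-1.0))

    def test_empty_candidate_zero(self):
        assert bleu2([], ["a"]) == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            bleu2(["a"], [])

    def test_word_order_sensitivity(self):
        ref = "a b c d".split()
        assert bleu2("d c b a".split(), ref) < bleu2(ref, ref)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cand, ref = _random_pair(rng)
            assert bleu2(cand, ref) == pytest.approx(bleu2_oracle(cand, ref), abs=1e-9)


class TestRouge:
    def test_identical_one(self):
        s = "ein zwei drei".split()
        assert rouge_recall(s, s) == 1.0

    def test_superset_candidate_scores_one(self):
        assert rouge_recall("a b c d extra mehr".split(), "a b c d".split()) == 1.0

    def test_hand_counted_recall(self):
        assert rouge_recall("a b".split(), "a b c d".split()) == 0.5

    def test_insensitive_to_order(self):
        ref = "a b c d".split()
        assert rouge_recall("d c b a".split(), ref) == 1.0

    def test_clipping_of_repeats(self):
        # candidate repeats 'a'; reference has it once
        assert rouge_recall("a a a".split(), "a b".split()) == 0.5

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            cand, ref = _random_pair(rng)
            assert rouge_recall(cand, ref) == pytest.approx(rouge_oracle(cand, ref), abs=1e-9)


class TestCoss:
    def test_identical_tokens_score_one(self, rng):
        emb = rng.normal(size=(10, 8))
        ids = [2, 5, 7]
        assert coss(ids, ids, emb) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_embeddings_score_zero(self):
        emb = np.zeros((4, 4))
        emb[0, 0] = 1.0  # candidate tokens on e1
        emb[1, 1] = 1.0  # reference tokens on e2
        assert coss([0, 0], [1, 1], emb) == 0.0

    def test_hand_computed_mean(self):
        # cosines 1.0 and 0.5 -> mean 0.75
        emb = np.array([[1.0, 0.0], [np.cos(np.pi / 3), np.sin(np.pi / 3)], [1.0, 0.0]])
        assert coss([0, 1], [2], emb) == pytest.approx(0.75, abs=1e-12)

    def test_negative_cosines_clamped(self):
        emb = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert coss([0], [1], emb) == 0.0

    def test_empty_inputs_zero(self, rng):
        emb = rng.normal(size=(4, 4))
        assert coss([], [1], emb) == 0.0
        assert coss([1], [], emb) == 0.0

    def test_order_insensitive(self, rng):
        emb = rng.normal(size=(10, 6))
        assert coss([1, 2, 3], [4, 5], emb) == pytest.approx(
            coss([3, 1, 2], [5, 4], emb))

    def test_positive_scaling_invariance(self):
        emb = np.array([[2.0, 2.0], [8.0, 8.0]])
        assert coss([0], [1], emb) == pytest.approx(1.0)


class TestMeteor:
    def test_identical_eight_tokens_closed_form(self):
        s = "a b c d e f g h".split()
        assert meteor(s, s) == pytest.approx(1.0 - 0.5 * (1 / 8) ** 3, abs=1e-15)

    def test_no_shared_tokens_zero(self):
        assert meteor(["a"], ["b"]) == 0.0

    def test_two_chunks_on_swapped_pair(self):
        # "b a" vs "a b": F=1, chunks=2, matches=2 -> 1 - 0.5 * 1 = 0.5
        assert meteor("b a".split(), "a b".split()) == pytest.approx(0.5)

    def test_recall_weighting(self):
        # missing reference words hurt more than extra candidate words
        ref = "a b c d e".split()
        miss = meteor("a b c".split(), ref)
        extra = meteor("a b c d e x y".split(), ref)
        assert extra > miss

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cand, ref = _random_pair(rng)
            assert 0.0 <= meteor(cand, ref) <= 1.0

    def test_word_order_sensitivity(self):
        ref = "a b c d".split()
        assert meteor("d c b a".split(), ref) < meteor(ref, ref)


class TestScoreReport:
    def _reports(self, texts_gen, texts_orig):
        mk = lambda rid, texts: Report(
            report_id=rid,
            sentences=[Sentence(text=t, keywords=["k"]) for t in texts])
        return mk("g", texts_gen), mk("o", texts_orig)

    @pytest.fixture()
    def emb(self, tiny_model):
        return tiny_model.embedding_table

    def test_self_scoring_maximal(self, tiny_corpus, tiny_vocab, emb):
        report = tiny_corpus.reports[0]
        mr = score_report(report, report, tiny_vocab, emb)
        assert mr.report_scores["BLEU2"] == pytest.approx(1.0)
        assert mr.report_scores["ROUGE"] == pytest.approx(1.0)
        assert mr.report_scores["COSS"] == pytest.approx(1.0, abs=1e-6)
        m = len(report.sentences[0].words())
        assert mr.sentence_scores[0]["METEOR"] == pytest.approx(1 - 0.5 * (1 / m) ** 3)

    def test_single_sentence_report_score_equals_sentence_score(self, tiny_vocab, emb):
        gen, orig = self._reports(["ein satz hier"], ["ein satz dort"])
        mr = score_report(gen, orig, tiny_vocab, emb)
        for name, v in mr.report_scores.items():
            assert v == pytest.approx(mr.sentence_scores[0][name])

    def test_scrambled_words_rouge_stays_one_bleu_drops(self, tiny_vocab, emb):
        orig_text = "alpha beta gamma delta epsilon"
        scrambled = "epsilon delta gamma beta alpha"
        gen, orig = self._reports([scrambled], [orig_text])
        mr = score_report(gen, orig, tiny_vocab, emb)
        assert mr.report_scores["ROUGE"] == pytest.approx(1.0)
        assert mr.report_scores["BLEU2"] < 1.0

    def test_unequal_sentence_counts_rejected(self, tiny_vocab, emb):
        gen, orig = self._reports(["eins"], ["eins", "zwei"])
        with pytest.raises(ValueError, match="mismatch"):
            score_report(gen, orig, tiny_vocab, emb)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_all_metrics_bounded(self, seed):
        rng = np.random.default_rng(seed)
        cand, ref = _random_pair(rng)
        emb = rng.normal(size=(16, 4))
        cids = list(rng.integers(0, 16, size=len(cand)))
        rids = list(rng.integers(0, 16, size=len(ref)))
        for v in (bleu2(cand, ref), rouge_recall(cand, ref),
                  coss(cids, rids, emb), meteor(cand, ref)):
            assert 0.0 <= v <= 1.0
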