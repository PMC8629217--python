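import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radeval import (
    Bleu,
    Cider,
    Meteor,
    NGramIndex,
    ParallelCorpus,
    Record,
    Report,
    RougeL,
    bleu,
    brevity_penalty,
    cider,
    evaluate_all,
    meteor,
    ngram_counts,
    rouge_l,
)
from radeval.baselines import _ClippedCountTable

from conftest import random_reports


def pair_corpus(pairs):
    return ParallelCorpus(
        tuple(
            Record(str(i), Report(tuple(r)), Report(tuple(c)))
            for i, (r, c) in enumerate(pairs)
        )
    )


tokens = st.lists(st.sampled_from("abcde"), min_size=1, max_size=12).map(tuple)


@pytest.mark.parametrize(
    "report, k, expected",
    [
        (("a", "b", "a"), 1, {("a",): 2, ("b",): 1}),
        (("a", "b", "a"), 2, {("a", "b"): 1, ("b", "a"): 1}),
        (("a", "b"), 3, {}),
    ],
)
def test_ngram_counts_sliding_window(report, k, expected):
    assert dict(ngram_counts(Report(report), k)) == expected


def test_brevity_penalty_values():
    assert brevity_penalty(4, 4) == 1.0
    assert brevity_penalty(8, 4) == 1.0
    assert abs(brevity_penalty(2, 4) - math.exp(-1)) < 1e-12
    assert brevity_penalty(0, 4) == 0.0
    # strictly decreasing once the candidate side is shorter
    assert brevity_penalty(3, 4) > brevity_penalty(2, 4) > brevity_penalty(1, 4)


class TestBleu:
    def test_identical_corpora(self):
        corpus = pair_corpus(
            [(("a", "b", "c", "d", "e"), ("a", "b", "c", "d", "e")), (("d", "e", "f", "g"), ("d", "e", "f", "g"))]
        )
        for k in range(1, 5):
            assert bleu(corpus, k=k, dialect="coco").corpus_score == pytest.approx(1.0)
        # the printed formula normalises every precision by total tokens, so
        # only the unigram precision reaches 1 on identical corpora
        assert bleu(corpus, k=1, dialect="paper").corpus_score == pytest.approx(1.0)
        assert bleu(corpus, k=4, dialect="paper").corpus_score <= 4.0

    def test_disjoint_corpora_score_zero(self):
        corpus = pair_corpus([(("a", "b"), ("c", "d"))])
        for dialect in ("paper", "coco"):
            assert bleu(corpus, k=2, dialect=dialect).corpus_score == 0.0

    def test_single_pair_paper_dialect_worked_example(self):
        corpus = pair_corpus([(("the", "cat"), ("the", "cat", "sat"))])
        assert bleu(corpus, k=1, dialect="paper").corpus_score == pytest.approx(2 / 3, abs=1e-12)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            Bleu(k=0)

    def test_record_order_invariance(self):
        pairs = [
            (("a", "b", "c"), ("a", "c")),
            (("d", "e"), ("d", "e", "a")),
            (("a", "a", "b"), ("a", "b", "b")),
        ]
        fwd = pair_corpus(pairs)
        rev = pair_corpus(pairs[::-1])
        for dialect in ("paper", "coco"):
            assert (
                bleu(fwd, k=3, dialect=dialect).corpus_score
                == bleu(rev, k=3, dialect=dialect).corpus_score
            )

    def test_clipping_monotone_under_token_removal(self):
        """Dropping candidate tokens never increases pooled clipped numerators."""
        refs = random_reports(7, 12, lo=3, hi=10)
        cands = random_reports(8, 12, lo=3, hi=10)
        metric = Bleu(k=2)
        full = metric.item_stats(refs, cands).sum(axis=0)
        shorter = [Report(c.tokens[:-1]) if len(c) > 1 else c for c in cands]
        less = metric.item_stats(refs, shorter).sum(axis=0)
        assert np.all(less[2:4] <= full[2:4])

    def test_table_counts_match_brute_force(self):
        """Corpus-clipped counts from the k-gram table equal per-pair recounts."""
        for seed in (0, 1, 2):
            refs = random_reports(seed, 40, lo=2, hi=12)
            table = _ClippedCountTable(refs, 3)
            rng_reports = random_reports(seed + 100, 5, lo=2, hi=12)
            for cand in rng_reports:
                for k in (1, 2, 3):
                    cc = ngram_counts(cand, k)
                    fast = sum(table.clipped_total(g, n, k) for g, n in cc.items())
                    brute = sum(
                        min(n, ngram_counts(r, k).get(g, 0))
                        for r in refs
                        for g, n in cc.items()
                    )
                    assert fast == brute


class TestRougeL:
    def test_worked_example(self):
        corpus = pair_corpus([(("a", "b", "c"), ("a", "c"))])
        b2 = 1.2**2
        expected = (1 + b2) * 1.0 * (2 / 3) / (b2 * 1.0 + 2 / 3)
        assert rouge_l(corpus).corpus_score == pytest.approx(expected, abs=1e-12)

    def test_identity_and_disjoint(self):
        assert rouge_l(pair_corpus([(("a", "b"), ("a", "b"))])).corpus_score == pytest.approx(1.0)
        assert rouge_l(pair_corpus([(("a", "b"), ("c", "d"))])).corpus_score == 0.0

    @given(tokens, tokens)
    def test_pair_score_in_unit_interval(self, r, c):
        score = RougeL().pair_score(Report(c), Report(r))
        assert 0.0 <= score <= 1.0


class TestMeteor:
    @pytest.mark.parametrize(
        "ref, cand, expected",
        [
            (("a", "b", "c", "d"), ("a", "b", "c", "d"), 0.9921875),
            (("a",), ("a",), 0.5),
            (("a", "b"), ("c", "d"), 0.0),
        ],
    )
    def test_worked_examples(self, ref, cand, expected):
        assert meteor(pair_corpus([(ref, cand)])).corpus_score == pytest.approx(
            expected, abs=1e-12
        )

    def test_chunks_penalise_scrambled_order(self):
        aligned = meteor(pair_corpus([(("a", "b", "c", "d"), ("a", "b", "c", "d"))]))
        scrambled = meteor(pair_corpus([(("a", "b", "c", "d"), ("b", "a", "d", "c"))]))
        assert scrambled.corpus_score < aligned.corpus_score

    @given(tokens, tokens)
    def test_pair_score_in_unit_interval(self, r, c):
        score = Meteor().pair_score(Report(c), Report(r))
        assert 0.0 <= score <= 1.0


class TestCider:
    def test_identical_pair_plain_is_one(self):
        # two references with partly distinct vocabulary: every k-gram of each
        # report misses the other report, so all idf weights are positive
        r1 = ("a", "b", "c", "d", "e")
        r2 = ("f", "g", "h", "i", "j")
        corpus = pair_corpus([(r1, r1), (r2, r2)])
        res = cider(corpus, k=4, variant="plain")
        assert res.corpus_score == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_pair_is_zero(self):
        refs = [Report(("a", "b", "c")), Report(("d", "e", "f"))]
        index = NGramIndex.build(refs, 2)
        for variant in ("plain", "d"):
            metric = Cider(k=2, variant=variant, index=index)
            assert metric.pair_score(refs[1], refs[0]) == 0.0

    def test_gram_in_every_reference_has_zero_idf(self):
        refs = [Report(("shared", "tail", x)) for x in ("a", "b", "c")]
        index = NGramIndex.build(refs, 2)
        assert index.idf(("shared",)) == 0.0
        assert index.idf(("shared", "tail")) == 0.0
        assert index.idf(("a",)) > 0

    def test_ciderd_range_and_length_penalty(self):
        refs = random_reports(3, 20, lo=3, hi=12)
        cands = random_reports(4, 20, lo=3, hi=12)
        metric = Cider(k=4, variant="d")
        stats = metric.item_stats(refs, cands)
        assert np.all(stats[:, 0] >= 0.0) and np.all(stats[:, 0] <= 10.0)
        # same content, mismatched length: penalty strictly reduces the score
        index = NGramIndex.build(refs, 1)
        short = Cider(k=1, variant="d", index=index)
        a = Report(("a", "b", "c"))
        b = Report(("a", "b", "c", "a", "b", "c", "a", "b", "c"))
        assert short.pair_score(b, a) < short.pair_score(a, a)


class TestNGramIndex:
    def test_index_invariants(self):
        reports = random_reports(11, 30, lo=1, hi=12)
        index = NGramIndex.build(reports, 3)
        assert sum(index.counts[1].values()) == sum(len(r) for r in reports)
        for k in (1, 2, 3):
            for g, df in index.doc_freq[k].items():
                assert 1 <= df <= index.n_reports
                assert index.counts[k][g] >= df
                assert (index.idf(g) == 0.0) == (df == index.n_reports)


class TestEvaluateAll:
    def test_identical_corpus_scores(self):
        corpus = pair_corpus(
            [((w, "a", "b", "c", "d"), (w, "a", "b", "c", "d")) for w in ("u", "v", "w")]
        )
        results = evaluate_all(
            corpus, ["bleu-1", "bleu-2", "bleu-3", "bleu-4", "rouge-l", "meteor"]
        )
        by_name = {r.name: r.corpus_score for r in results}
        for k in range(1, 5):
            assert by_name[f"bleu-{k}"] == pytest.approx(1.0)
        assert by_name["rouge-l"] == pytest.approx(1.0)

    def test_deterministic_and_empty_spec(self):
        corpus = pair_corpus([(("a", "b"), ("a", "c")), (("d",), ("d",))])
        spec = ["bleu-2", "rouge-l", "meteor", "cider-d"]
        first = [r.corpus_score for r in evaluate_all(corpus, spec)]
        second = [r.corpus_score for r in evaluate_all(corpus, spec)]
        assert first == second
        assert evaluate_all(corpus, []) == []

    def test_unknown_metric_errors(self):
        corpus = pair_corpus([(("a",), ("a",))])
        with pytest.raises(ValueError, match="unknown metric"):
            evaluate_all(corpus, ["spice"])
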