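import logging
import math

import pytest

from promptgauge import (
    ConsistencyResult,
    ContractViolationError,
    EvalItem,
    InputError,
    OptimizationConfig,
    PromptCandidate,
    build_paraphrase_pool,
    compute_perplexity,
    cosine_similarity,
    embed,
    geometric_mean_likelihood,
    optimize,
    rank_by_perplexity,
    score_self_consistency,
    select_optimal,
    select_top_k,
)
from promptgauge.backends import EchoGenerator, TokenScoreSequence, UniformScorer


class SequenceScorer:
    """Returns preset logprobs for any text (one per whitespace token)."""

    name = "seq-stub"

    def __init__(self, logprobs):
        self.logprobs = tuple(logprobs)

    def score_tokens(self, text):
        toks = tuple(text.split())
        assert len(toks) == len(self.logprobs)
        return TokenScoreSequence(tokens=toks, logprobs=self.logprobs)


class PerTextScorer:
    """Maps full text -> fixed perplexity via a single-token logprob."""

    name = "per-text-stub"

    def __init__(self, perplexities):
        self.perplexities = dict(perplexities)

    def score_tokens(self, text):
        ppl = self.perplexities[text]
        return TokenScoreSequence(tokens=(text,), logprobs=(-math.log(ppl),))


class TestPerplexity:
    def test_uniform_half_gives_two(self):
        assert compute_perplexity("a b c d", UniformScorer(0.5)) == pytest.approx(2.0)

    def test_certain_token_gives_one(self):
        assert compute_perplexity("hello", UniformScorer(1.0)) == pytest.approx(1.0)

    def test_hand_computed_geometric_mean(self):
        # (0.1 * 0.2 * 0.4)^(-1/3) = 5.0
        scorer = SequenceScorer([math.log(0.1), math.log(0.2), math.log(0.4)])
        assert compute_perplexity("a b c", scorer) == pytest.approx(5.0)

    def test_uniform_stub_perplexity_equals_branching_factor(self):
        for p in (0.5, 0.25, 0.1):
            assert compute_perplexity("w x y z", UniformScorer(p)) == pytest.approx(1 / p)

    def test_geometric_mean_likelihood_is_reciprocal(self):
        scorer = UniformScorer(0.25)
        assert geometric_mean_likelihood("a b", scorer) == pytest.approx(0.25)

    def test_always_at_least_one(self, scorer):
        for text in ("the", "zyzzyva qwerty", "thank you for your message"):
            assert compute_perplexity(text, scorer) >= 1.0

    def test_positive_logprob_rejected(self):
        class BadSeq:
            tokens = ("a",)
            logprobs = (0.5,)

        class BadScorer:
            name = "bad"

            def score_tokens(self, text):
                return BadSeq()

        with pytest.raises(ContractViolationError):
            compute_perplexity("a", BadScorer())

    def test_empty_text_rejected(self, scorer):
        with pytest.raises(InputError):
            compute_perplexity("", scorer)


class TestParaphrasePool:
    def test_default_pool_includes_seed(self, generator, seed_prompt):
        pool = build_paraphrase_pool(seed_prompt, 20, generator, seed=1)
        assert len(pool) == 21
        assert sum(c.source == "seed" for c in pool) == 1
        assert all(c.instruction_text for c in pool)

    def test_echo_generator_deduplicates_with_warning(self, seed_prompt, caplog):
        with caplog.at_level(logging.WARNING):
            pool = build_paraphrase_pool(seed_prompt, 1, EchoGenerator(), seed=0)
        assert len(pool) == 1  # paraphrase == seed, de-duplicated
        assert "de-duplication" in caplog.text or "duplicate" in caplog.text

    def test_fixed_seed_reproducible(self, generator, seed_prompt):
        a = build_paraphrase_pool(seed_prompt, 10, generator, seed=9)
        b = build_paraphrase_pool(seed_prompt, 10, generator, seed=9)
        assert a == b

    def test_invalid_inputs(self, generator):
        with pytest.raises(InputError):
            build_paraphrase_pool("", 5, generator, seed=0)
        with pytest.raises(InputError):
            build_paraphrase_pool("x", 0, generator, seed=0)


def _cand(cid, text, source="paraphrase", ppl=None):
    return PromptCandidate(candidate_id=cid, instruction_text=text, source=source, perplexity=ppl)


class TestRankingAndSelection:
    def test_ascending_order(self):
        scorer = PerTextScorer({"a": 5.0, "b": 2.0, "c": 9.0})
        ranked = rank_by_perplexity([_cand("1", "a"), _cand("2", "b"), _cand("3", "c")], scorer)
        assert [c.perplexity for c in ranked] == pytest.approx([2.0, 5.0, 9.0])
        assert all(c.perplexity is not None for c in ranked)

    def test_tie_breaks_seed_first(self):
        scorer = PerTextScorer({"a": 3.0, "b": 3.0})
        ranked = rank_by_perplexity(
            [_cand("zz", "a"), _cand("aa", "b", source="seed")], scorer
        )
        assert ranked[0].source == "seed"

    def test_top_k_identity_and_minimum(self):
        scorer = PerTextScorer({"a": 5.0, "b": 2.0, "c": 9.0})
        ranked = rank_by_perplexity([_cand("1", "a"), _cand("2", "b"), _cand("3", "c")], scorer)
        assert select_top_k(ranked, 3) == ranked
        assert select_top_k(ranked, 1)[0].perplexity == pytest.approx(2.0)

    def test_top_k_boundary_property(self, generator, scorer, seed_prompt):
        pool = build_paraphrase_pool(seed_prompt, 20, generator, seed=3)
        ranked = rank_by_perplexity(pool, scorer)
        selected = select_top_k(ranked, 5)
        assert len(selected) == 5
        rejected = ranked[5:]
        assert max(c.perplexity for c in selected) <= min(c.perplexity for c in rejected)

    def test_k_exceeding_pool_rejected(self):
        with pytest.raises(InputError):
            select_top_k([_cand("1", "a", ppl=2.0)], 2)


class TestSelfConsistency:
    def test_perfect_generator_scores_100(self, eval_items, embedder, static_generator_factory):
        # generator that returns item 0's ground truth verbatim; score only item 0
        gen = static_generator_factory(eval_items[0].ground_truth_response)
        res = score_self_consistency(
            _cand("c1", "Reply to <User Message> kindly."),
            eval_items[:1], gen, embedder, n_generations=3, seed=0,
        )
        assert res.similarities == pytest.approx((1.0, 1.0, 1.0))
        assert res.mean_score == pytest.approx(100.0)

    def test_round_robin_covers_items(self, eval_items, embedder, static_generator_factory):
        gen = static_generator_factory("some generic reply text")
        res = score_self_consistency(
            _cand("c1", "x <User Message>"), eval_items, gen, embedder,
            n_generations=4, seed=0,
        )
        assert len(res.similarities) == 4

    def test_closer_generator_scores_higher_with_hand_computed_cosines(
        self, eval_items, embedder, static_generator_factory
    ):
        truth = eval_items[0].ground_truth_response
        close_text = truth.replace("normal", "usual")
        far_text = "completely unrelated words about gardening and weather"
        res_close = score_self_consistency(
            _cand("A", "t <User Message>"), eval_items[:1],
            static_generator_factory(close_text), embedder, 2, seed=0,
        )
        res_far = score_self_consistency(
            _cand("B", "t <User Message>"), eval_items[:1],
            static_generator_factory(far_text), embedder, 2, seed=0,
        )
        truth_vec = embed(truth, embedder)
        assert res_close.similarities[0] == pytest.approx(
            cosine_similarity(embed(close_text, embedder), truth_vec)
        )
        assert res_far.similarities[0] == pytest.approx(
            cosine_similarity(embed(far_text, embedder), truth_vec)
        )
        assert res_close.mean_score > res_far.mean_score

    def test_25_scored_outputs_for_5x5(self, eval_items, generator, embedder):
        cands = [_cand(f"c{i}", f"variant {i} of <User Message>") for i in range(5)]
        results = [
            score_self_consistency(c, eval_items, generator, embedder, 5, seed=1)
            for c in cands
        ]
        assert sum(len(r.similarities) for r in results) == 25

    def test_requires_items_and_generations(self, generator, embedder):
        with pytest.raises(InputError):
            score_self_consistency(_cand("c", "x"), [], generator, embedder, 1, 0)


class TestSelectOptimal:
    def test_single_candidate(self):
        c = _cand("only", "text", ppl=2.0)
        r = ConsistencyResult("only", (0.9,), 90.0)
        winner, res = select_optimal([r], [c])
        assert winner is c and res is r

    def test_highest_mean_wins(self):
        cands = [_cand(f"c{i}", f"t{i}", ppl=2.0 + i) for i in range(3)]
        results = [
            ConsistencyResult("c0", (0.98,), 98.0),
            ConsistencyResult("c1", (0.991,), 99.1),
            ConsistencyResult("c2", (0.972,), 97.2),
        ]
        winner, res = select_optimal(results, cands)
        assert winner.candidate_id == "c1"
        assert res.mean_score == pytest.approx(99.1)

    def test_tie_breaks_to_lower_perplexity(self):
        cands = [_cand("x", "tx", ppl=3.1), _cand("y", "ty", ppl=2.8)]
        results = [ConsistencyResult("x", (0.9,), 90.0), ConsistencyResult("y", (0.9,), 90.0)]
        winner, _ = select_optimal(results, cands)
        assert winner.candidate_id == "y"

    def test_mismatched_ids_rejected(self):
        with pytest.raises(InputError):
            select_optimal([ConsistencyResult("a", (0.5,), 50.0)], [_cand("b", "t")])

    def test_mean_score_consistency_enforced(self):
        with pytest.raises(InputError):
            ConsistencyResult("a", (0.5, 0.7), 90.0)


class TestOptimizePipeline:
    def test_default_audit_shape(self, generator, scorer, embedder, seed_prompt, few_shot, eval_items):
        res = optimize(
            seed_prompt, few_shot, eval_items, OptimizationConfig(seed=11),
            generator, scorer, embedder,
        )
        assert res.audit["pool_size"] == 21
        assert len(res.audit["perplexities"]) == 21
        assert len(res.audit["consistency"]) == 5
        assert res.audit["n_generations_total"] == 25

    def test_minimal_config(self, generator, scorer, embedder, seed_prompt, few_shot, eval_items):
        cfg = OptimizationConfig(n_paraphrases=2, k_lowest=1, n_generations_per_candidate=1,
                                 seed=0, include_seed_prompt=False)
        res = optimize(seed_prompt, few_shot, eval_items, cfg, generator, scorer, embedder)
        assert len(res.consistency.similarities) == 1
        assert res.winning_candidate.perplexity is not None

    def test_fixed_seed_identical_result(self, generator, scorer, embedder, seed_prompt, few_shot, eval_items):
        cfg = OptimizationConfig(n_paraphrases=6, k_lowest=3, n_generations_per_candidate=2, seed=21)
        a = optimize(seed_prompt, few_shot, eval_items, cfg, generator, scorer, embedder)
        b = optimize(seed_prompt, few_shot, eval_items, cfg, generator, scorer, embedder)
        assert a.audit == b.audit
        assert a.winning_candidate == b.winning_candidate

    def test_argmax_invariant(self, generator, scorer, embedder, seed_prompt, few_shot, eval_items):
        res = optimize(
            seed_prompt, few_shot, eval_items,
            OptimizationConfig(n_paraphrases=8, k_lowest=4, n_generations_per_candidate=2, seed=5),
            generator, scorer, embedder,
        )
        best = res.consistency.mean_score
        assert all(r["mean_score"] <= best for r in res.audit["consistency"])

    def test_monotonicity_closer_generator_never_scores_lower(
        self, embedder, eval_items, static_generator_factory
    ):
        truth = eval_items[0].ground_truth_response
        gen_exact = static_generator_factory(truth)
        gen_noisy = static_generator_factory(truth.replace("results", "onions").replace("normal", "blue"))
        cand = _cand("c", "Reply to <User Message>.")
        exact = score_self_consistency(cand, eval_items[:1], gen_exact, embedder, 3, 0)
        noisy = score_self_consistency(cand, eval_items[:1], gen_noisy, embedder, 3, 0)
        assert exact.mean_score >= noisy.mean_score

    def test_invalid_config_rejected(self):
        with pytest.raises(InputError):
            OptimizationConfig(n_paraphrases=2, k_lowest=5)
        with pytest.raises(InputError):
            OptimizationConfig(n_generations_per_candidate=0)

    def test_stage_error_annotated(self, generator, scorer, embedder, few_shot, eval_items):
        class FailingEmbedder:
            name = "boom"
            dim = 4

            def embed(self, text):
                raise RuntimeError("exploded")

        with pytest.raises(Exception) as exc:
            optimize(
                "seed prompt <User Message>", few_shot, eval_items,
                OptimizationConfig(n_paraphrases=2, k_lowest=1, n_generations_per_candidate=1),
                generator, scorer, FailingEmbedder(),
            )
        assert "score_self_consistency" in str(exc.value)
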