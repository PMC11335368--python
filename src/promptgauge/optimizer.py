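"""Prompt-optimization pipeline.

Given a seed instruction written naïvely by a subject-matter expert, the
pipeline:

1. paraphrases it ``n_paraphrases`` times (default 20) with the generator
   backend, keeping the seed itself in the candidate pool;
2. scores every candidate's **perplexity** under the likelihood backend and
   ranks ascending — lower perplexity means the instruction is less
   "surprising" to the model, i.e. carries less metalinguistic overhead;
3. keeps the ``k_lowest`` candidates (default 5);
4. composes each survivor with few-shot examples and scores its
   **self-consistency**: ``n_generations_per_candidate`` outputs (default 5,
   so 25 generations in the default configuration) are generated round-robin
   across the ground-truth evaluation items, each output is embedded, and its
   cosine similarity to the embedding of the item's ground-truth response is
   recorded;
5. selects the candidate with the highest mean similarity (reported on a
   0-100 scale), breaking ties by lower perplexity then candidate id.

Perplexity here is ``exp(-(1/T) * sum(logprob_i))`` over the T scored tokens
— the exponential of the mean negative log-likelihood — and is bounded below
by 1.  The geometric-mean token likelihood (its reciprocal) is exposed
read-only for reporting; ranking always follows lowest perplexity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .backends import (
    EmbedderBackend,
    GenerationRequest,
    GeneratorBackend,
    ScorerBackend,
    cosine_similarity,
    embed,
    generate,
    score_tokens,
    stable_subseed,
)
from .errors import InputError, PromptGaugeError
from .template import FewShotExample, PromptTemplate, parse_template, render
from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PromptCandidate",
    "EvalItem",
    "ConsistencyResult",
    "OptimizationConfig",
    "OptimizedPrompt",
    "build_paraphrase_pool",
    "compute_perplexity",
    "geometric_mean_likelihood",
    "rank_by_perplexity",
    "select_top_k",
    "score_self_consistency",
    "select_optimal",
    "optimize",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromptCandidate:
    """One candidate instruction text with provenance and (once scored)
    its perplexity."""

    candidate_id: str
    instruction_text: str
    source: str  # "seed" | "paraphrase"
    perplexity: float | None = None

    def __post_init__(self) -> None:
        if not self.instruction_text:
            raise InputError("instruction_text must be non-empty")
        if self.source not in ("seed", "paraphrase"):
            raise InputError(f"source must be 'seed' or 'paraphrase', got {self.source!r}")
        if self.perplexity is not None and self.perplexity < 1.0:
            raise InputError("perplexity, once set, must be >= 1")


@dataclass(frozen=True)
class EvalItem:
    """A ground-truth evaluation item: patient message, exemplar response,
    and the EHR context record for slot substitution."""

    item_id: str
    user_message: str
    ground_truth_response: str
    ehr_context: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.user_message or not self.ground_truth_response:
            raise InputError("user_message and ground_truth_response must be non-empty")


@dataclass(frozen=True)
class ConsistencyResult:
    """Per-candidate self-consistency: one cosine similarity per generated
    output, and the mean on a 0-100 scale."""

    candidate_id: str
    similarities: tuple[float, ...]
    mean_score: float

    def __post_init__(self) -> None:
        if not self.similarities:
            raise InputError("at least one similarity required")
        if any(not (-1.0 <= s <= 1.0) for s in self.similarities):
            raise InputError("similarities must lie in [-1, 1]")
        expected = 100.0 * (sum(self.similarities) / len(self.similarities))
        if abs(self.mean_score - expected) > 1e-9:
            raise InputError("mean_score inconsistent with similarities")


@dataclass(frozen=True)
class OptimizationConfig:
    """Pipeline sizes; defaults give 20 paraphrases + seed, top 5, and
    5 x 5 = 25 scored generations."""

    n_paraphrases: int = 20
    k_lowest: int = 5
    n_generations_per_candidate: int = 5
    seed: int = 0
    include_seed_prompt: bool = True

    def __post_init__(self) -> None:
        if self.n_paraphrases < 1 or self.k_lowest < 1 or self.n_generations_per_candidate < 1:
            raise InputError("pipeline sizes must be positive")
        pool = self.n_paraphrases + (1 if self.include_seed_prompt else 0)
        if self.k_lowest > pool:
            raise InputError(
                f"k_lowest={self.k_lowest} exceeds candidate pool size {pool}"
            )


@dataclass(frozen=True)
class OptimizedPrompt:
    """The pipeline's product: the winning candidate, a renderable template
    built from it, its consistency result, and the full audit trail."""

    winning_candidate: PromptCandidate
    template: PromptTemplate
    consistency: ConsistencyResult
    audit: dict


# ---------------------------------------------------------------------------
# stage 1: paraphrase pool
# ---------------------------------------------------------------------------

def build_paraphrase_pool(
    seed_prompt: str,
    n: int,
    generator: GeneratorBackend,
    seed: int,
    include_seed_prompt: bool = True,
) -> list[PromptCandidate]:
    """Generate ``n`` paraphrase candidates (plus the seed prompt itself when
    configured), de-duplicating identical texts with a warning."""
    if not seed_prompt:
        raise InputError("seed_prompt must be non-empty")
    if n < 1:
        raise InputError("n must be >= 1")
    request = GenerationRequest(
        prompt_text=seed_prompt,
        n_samples=n,
        temperature=1.0,
        max_new_tokens=500,
        seed=stable_subseed(seed, "paraphrase"),
    )
    texts = generate(request, generator)
    candidates: list[PromptCandidate] = []
    if include_seed_prompt:
        candidates.append(
            PromptCandidate(candidate_id="seed", instruction_text=seed_prompt, source="seed")
        )
    width = len(str(n))
    for i, text in enumerate(texts, start=1):
        candidates.append(
            PromptCandidate(
                candidate_id=f"p{i:0{width}d}", instruction_text=text, source="paraphrase"
            )
        )
    seen: dict[str, str] = {}
    unique: list[PromptCandidate] = []
    for c in candidates:
        if c.instruction_text in seen:
            logger.warning(
                "duplicate paraphrase %s == %s dropped", c.candidate_id, seen[c.instruction_text]
            )
            continue
        seen[c.instruction_text] = c.candidate_id
        unique.append(c)
    if len(unique) < len(candidates):
        logger.warning(
            "candidate pool reduced from %d to %d after de-duplication",
            len(candidates), len(unique),
        )
    logger.info("paraphrase pool size: %d", len(unique))
    return unique


# ---------------------------------------------------------------------------
# stage 2: perplexity ranking
# ---------------------------------------------------------------------------

def compute_perplexity(text: str, scorer: ScorerBackend) -> float:
    """``exp(-mean logprob)`` over the scored tokens; always >= 1."""
    if not text:
        raise InputError("cannot compute perplexity of empty text")
    seq = score_tokens(text, scorer)
    if any(lp > 0 for lp in seq.logprobs):  # guard against duck-typed scorers
        from .errors import ContractViolationError

        raise ContractViolationError("scorer returned a positive log-probability")
    mean_lp = sum(seq.logprobs) / len(seq.logprobs)
    return math.exp(-mean_lp)


def geometric_mean_likelihood(text: str, scorer: ScorerBackend) -> float:
    """Geometric mean of per-token probabilities (= 1 / perplexity).

    Read-only companion score on the (0, 1] likelihood scale; ranking always
    uses perplexity.
    """
    return 1.0 / compute_perplexity(text, scorer)


def _rank_key(c: PromptCandidate) -> tuple:
    return (c.perplexity, 0 if c.source == "seed" else 1, c.candidate_id)


def rank_by_perplexity(
    candidates: Sequence[PromptCandidate], scorer: ScorerBackend
) -> list[PromptCandidate]:
    """Score and sort candidates ascending by perplexity.

    Ties break seed-first, then by candidate id, so ranking is deterministic.
    """
    scored = [
        replace(c, perplexity=compute_perplexity(c.instruction_text, scorer))
        for c in candidates
    ]
    return sorted(scored, key=_rank_key)


def select_top_k(ranking: Sequence[PromptCandidate], k: int) -> list[PromptCandidate]:
    """First ``k`` of an ascending perplexity ranking."""
    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(ranking):
        raise InputError(f"k={k} exceeds pool size {len(ranking)}")
    return list(ranking[:k])


# ---------------------------------------------------------------------------
# stage 3: self-consistency scoring
# ---------------------------------------------------------------------------

def _compose_prompt(
    candidate: PromptCandidate,
    item: EvalItem,
    few_shot: Sequence[FewShotExample],
) -> str:
    """Render the full prompt for one candidate and one evaluation item.

    If the candidate text is a well-formed template (contains the
    user-message placeholder), it is rendered with the item's EHR context,
    slots absent from the context left as markers.  Paraphrasing can mangle
    the placeholder; such candidates fall back to instruction + examples +
    message concatenation so they can still be scored (and lose fairly).
    """
    try:
        tmpl = parse_template(candidate.instruction_text)
        missing = frozenset(s for s in tmpl.slots if s not in item.ehr_context)
        return render(
            tmpl, item.ehr_context, item.user_message, few_shot, optional_slots=missing
        )
    except FormatError:
        parts = [candidate.instruction_text]
        if few_shot:
            from .template import _render_examples  # noqa: PLC0415

            parts.append(_render_examples(few_shot))
        parts.append(item.user_message)
        return "\n".join(parts)


def score_self_consistency(
    candidate: PromptCandidate,
    eval_items: Sequence[EvalItem],
    generator: GeneratorBackend,
    embedder: EmbedderBackend,
    n_generations: int,
    seed: int,
    few_shot: Sequence[FewShotExample] = (),
) -> ConsistencyResult:
    """Generate ``n_generations`` outputs for one candidate (round-robin over
    the evaluation items) and score each against its item's ground truth by
    embedding cosine similarity; mean is reported on the 0-100 scale."""
    if not eval_items:
        raise InputError("eval_items must be non-empty")
    if n_generations < 1:
        raise InputError("n_generations must be >= 1")
    sims: list[float] = []
    for g in range(n_generations):
        item = eval_items[g % len(eval_items)]
        prompt = _compose_prompt(candidate, item, few_shot)
        request = GenerationRequest(
            prompt_text=prompt,
            n_samples=1,
            temperature=1.0,
            max_new_tokens=500,
            seed=stable_subseed(seed, "consistency", candidate.candidate_id, g),
        )
        output = generate(request, generator)[0]
        sim = cosine_similarity(
            embed(output, embedder), embed(item.ground_truth_response, embedder)
        )
        sims.append(sim)
    mean = 100.0 * (sum(sims) / len(sims))
    return ConsistencyResult(
        candidate_id=candidate.candidate_id, similarities=tuple(sims), mean_score=mean
    )


# ---------------------------------------------------------------------------
# stage 4: selection
# ---------------------------------------------------------------------------

def select_optimal(
    results: Sequence[ConsistencyResult],
    candidates: Sequence[PromptCandidate],
) -> tuple[PromptCandidate, ConsistencyResult]:
    """Pick the candidate maximizing mean consistency score.

    Ties break toward lower perplexity, then lexicographic candidate id.
    """
    if not results:
        raise InputError("results must be non-empty")
    by_id = {c.candidate_id: c for c in candidates}
    if set(r.candidate_id for r in results) != set(by_id):
        raise InputError("consistency results do not match candidate ids")
    if len(results) != len(by_id):
        raise InputError("exactly one result per candidate required")

    def key(r: ConsistencyResult) -> tuple:
        c = by_id[r.candidate_id]
        ppl = c.perplexity if c.perplexity is not None else math.inf
        return (-r.mean_score, ppl, r.candidate_id)

    best = min(results, key=key)
    return by_id[best.candidate_id], best


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _template_from(candidate_text: str, seed_prompt: str) -> PromptTemplate:
    for text in (candidate_text, seed_prompt):
        try:
            return parse_template(text)
        except (FormatError, InputError):
            continue
    # neither text carries a placeholder: append one
    return parse_template(candidate_text + "\n<User Message>")


def optimize(
    seed_prompt: str,
    few_shot: Sequence[FewShotExample],
    eval_items: Sequence[EvalItem],
    config: OptimizationConfig,
    generator: GeneratorBackend,
    scorer: ScorerBackend,
    embedder: EmbedderBackend,
) -> OptimizedPrompt:
    """Run the full pipeline and return the winner plus a machine-readable
    audit of every intermediate score."""
    if not eval_items:
        raise InputError("eval_items must be non-empty")

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PromptGaugeError as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc

    pool = stage(
        "build_paraphrase_pool",
        build_paraphrase_pool,
        seed_prompt, config.n_paraphrases, generator, config.seed,
        config.include_seed_prompt,
    )
    ranking = stage("rank_by_perplexity", rank_by_perplexity, pool, scorer)
    selected = stage("select_top_k", select_top_k, ranking, config.k_lowest)
    results = [
        stage(
            "score_self_consistency",
            score_self_consistency,
            c, eval_items, generator, embedder,
            config.n_generations_per_candidate, config.seed, few_shot,
        )
        for c in selected
    ]
    winner, winner_result = stage("select_optimal", select_optimal, results, selected)

    audit = {
        "config": {
            "n_paraphrases": config.n_paraphrases,
            "k_lowest": config.k_lowest,
            "n_generations_per_candidate": config.n_generations_per_candidate,
            "seed": config.seed,
            "include_seed_prompt": config.include_seed_prompt,
        },
        "pool_size": len(pool),
        "perplexities": [
            {
                "candidate_id": c.candidate_id,
                "source": c.source,
                "perplexity": c.perplexity,
                "geometric_mean_likelihood": 1.0 / c.perplexity,
            }
            for c in ranking
        ],
        "selected_ids": [c.candidate_id for c in selected],
        "consistency": [
            {
                "candidate_id": r.candidate_id,
                "similarities": list(r.similarities),
                "mean_score": r.mean_score,
            }
            for r in results
        ],
        "n_generations_total": sum(len(r.similarities) for r in results),
        "winner_id": winner.candidate_id,
    }
    return OptimizedPrompt(
        winning_candidate=winner,
        template=_template_from(winner.instruction_text, seed_prompt),
        consistency=winner_result,
        audit=audit,
    )
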