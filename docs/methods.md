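# Methods

## Prompt-optimization pipeline

The optimizer treats prompt selection as a two-stage filter. Stage one is
lexical: a generator backend paraphrases the seed instruction
`n_paraphrases` times (default 20), the seed itself stays in the pool
(configurable, default on), duplicates are dropped with a warning, and every
candidate is scored by perplexity under the likelihood backend,

    PPL(x) = exp( -(1/T) * sum_i log p(token_i | context) ),

the exponential of the mean negative log-likelihood over the T tokens, with
PPL >= 1 always. The `k_lowest` candidates (default 5) survive: low
perplexity operationalizes "less metalinguistic overhead", the intuition
being that an instruction the model finds unsurprising wastes less of its
capacity (and its token budget) on decoding the instruction itself. The
reciprocal — the geometric-mean token likelihood, on (0, 1] — is exposed
read-only for reporting because likelihood magnitudes are sometimes the more
natural scale; ranking always uses lowest perplexity. Perplexities are
backend-relative and are never compared across scorers.

Stage two is semantic: each survivor is composed with the few-shot examples
and scored by self-consistency against ground-truth items,
`n_generations_per_candidate` outputs (default 5, hence 25 scored
generations at the defaults) allocated round-robin across the evaluation
items so every item is covered when the counts match. Each output is
embedded and compared to the embedding of its item's reference reply by
cosine similarity; the candidate score is 100 x the mean similarity. The
argmax wins; ties break to lower perplexity, then lexicographic candidate
id, so a run is fully deterministic given its seed. An audit trail records
every intermediate score.

Candidates whose paraphrasing mangled the user-message placeholder can no
longer be rendered as templates; they are scored via plain concatenation
(instruction + examples + message) rather than excluded, so a destructive
paraphrase loses on merit instead of crashing the run.

## Backends

Three separate capability contracts (generator / token scorer / embedder)
rather than one monolithic "LLM" interface, because deployments use three
distinct models for these roles. The shipped defaults are deterministic
mocks: a seeded template-echo generator with temperature-scaled synonym
substitution and rare adjacent swaps (temperature 0 is a pure echo; the
request defaults, temperature 1.0 and a 500-token output cap, mirror the
production configuration being emulated); an add-one-smoothed unigram scorer
estimated from a small packaged corpus of generic clinic-reply prose, so
every log-probability is strictly negative; and a BLAKE2b-hashed character
3-gram count embedder, L2-normalized, dimension 256. The mock tokenizer is
whitespace over NFC-normalized text; real backends bring their own. No
global random state exists anywhere: all sub-streams derive from explicit
seeds via a stable BLAKE2b hash of (seed, purpose, id), each below 2^31.

## Edit metrics

Default distance is optimal string alignment (OSA): unit-cost insertions,
deletions, substitutions, adjacent transpositions, no substring edited
twice. This is what most string libraries ship under the name
"Damerau-Levenshtein"; the unrestricted Lowrance-Wagner variant (a true
metric, pointwise <= OSA) is available behind a flag, and the two are
distinguished by the canonical pair ("CA", "ABC"): 3 under OSA, 2
unrestricted. Distances run on NFC-normalized code points, case and
whitespace significant, all operations unit cost. Similarity is
1 - d/max(len); two empty strings get 1.0. The published band definitions
leave exactly 0.9999 unassigned (">0.9999" identical vs "<0.9999" nearly
identical); the package closes the upper band, so 0.9999 counts as
identical — a one-point-in-a-continuum convention that no realistic corpus
exercises (hitting it requires strings of 10,000+ characters).

## Analytics

Usage percentage is used/total generated per period; sentiment percentage is
thumbs-down negatives over seen messages (a rating requires the draft to
have been seen). The edit-category table counts used drafts by their
recomputed band and places every unused draft in "different": a discarded
draft is a fully edited one. The chi-square test is Pearson's without
continuity correction (the table is 4x2, not 2x2). The 2x2 odds ratio is
the direct cross-product estimate with a Wald interval on the log scale,
optionally Haldane-Anscombe-corrected (+0.5) for zero cells. It is a
marginal, unadjusted estimate and is documented as such: random-intercept
(GLMM/mixed-linear) adjusted effects are deliberately out of scope because
they require the original per-provider data and are a routine fit in
statsmodels or lme4 once events carry provider ids — which the corpus
format and the synthetic generator both preserve for that purpose.

All printed percentages pass through one rounding rule: half away from
zero, one decimal, computed in exact integer arithmetic. Published summary
tables are internally inconsistent with any single rounding rule in two
cells (1327/7605 prints as 17.5 where half-up gives 17.4; 468/3882 prints
as 12.0 where half-up gives 12.1); the package reports its own computed
roundings and treats the underlying integer counts, which reproduce
exactly, as the ground truth.

## Synthetic corpus

`generate_corpus` draws provider intercepts b_i ~ Normal(0, sd^2) on the
logit scale and uses each draft with probability
logistic(base + effect * [post] + b_i) — the same structure as the
logistic GLMM the analytics sidestep, so recovered marginal effects can be
benchmarked against known conditional truths. Defaults emulate a
two-period clinic deployment: 27 providers, ~140 drafts per provider per
period (Poisson counts), intercept sd 0.8, base usage ~19% with a modest
negative post-period effect, sentiment rates 0.12 pre and 0.082 post, and
a used-draft edit mix of (0.014, 0.139, 0.378, 0.469) over the four bands
— the mix implied by a corpus in which under 3% of drafts survive nearly
verbatim. Draft texts are word-salad from a tiny packaged vocabulary
(60-120 characters): clinical realism is a non-goal, only string-metric
and statistical structure matter, so passing tests say nothing about
linguistic quality of real drafts.

`apply_targeted_edits` inverts the band map: it picks an edit count k from
the band's target similarity (each mutation is one unit operation, so the
final distance is at most k), mutates, verifies the band by recomputation,
and retries with k adjusted, up to 20 attempts, deterministically per
seed. Very short texts make narrow bands unreachable (nearly-identical
needs roughly 40+ characters) and raise an input error.

`corpus_from_table` is the deterministic counterpart: given per-period
category cells, used counts and sentiment counts, it engineers events that
reproduce the table cell-for-cell, with used drafts beyond the first three
bands generated as heavily edited and the remaining "different" cell
filled by unused drafts. A `with_texts=False` switch skips text generation
for purely statistical experiments (e.g. repeated odds-ratio recovery),
where draft strings would only cost time.

The odds-ratio recovery check runs at 30 providers x 200 drafts with
intercept sd 0.2. The unadjusted odds ratio is a marginal estimand: with
substantial intercept variance it is attenuated relative to the
conditional (subject-specific) effect — non-collapsibility of the odds
ratio — so coverage of the conditional truth by the marginal Wald interval
is only a meaningful calibration check when heterogeneity is small. The
suite pins that regime; the attenuation itself is expected behaviour, not
a defect.

## Numerical and design choices

- Tie-breaks: perplexity ties rank the seed prompt first, then candidate
  id; consistency ties go to lower perplexity, then id. Deterministic
  builds were preferred wherever the ordering was otherwise unspecified.
- Cosine similarity raises on a zero-norm embedding (empty text) rather
  than defining 0/0; the mock embedder embeds only empty text to zero.
- Chi-square requires all-positive marginals; the CLI drops all-zero
  category rows before testing and warns, since small corpora routinely
  lack "identical" drafts.
- Templates: slot values are substituted inside their brackets (the
  rendered prompt shows `[Pat]`, matching the bracketed-EHR-data
  convention); few-shot blocks are ‖-delimited and precede the user
  message by default (placement configurable); unknown context keys warn
  rather than fail; missing required slots fail listing every missing
  name. Unicode is NFC-normalized at parse time for stable token counts
  and edit distances.
- Test problem sizes: the exhaustive edit-distance oracle runs breadth-first
  search over single edits for all string pairs up to length 3 on a 3-letter
  alphabet, an independent top-down OSA recursion for all pairs up to length
  4 and 1500-2000 random pairs up to length 6, with edlib as the external
  Levenshtein reference; these sizes already cover every branch of both
  dynamic programs (the discriminating configurations need <= 3 characters
  per side).

## Known limitations

- Mock backends exercise control flow and determinism, not language
  quality; self-consistency scores from the 3-gram embedder are not
  comparable to sentence-encoder scores.
- Real-model adapters (hosted chat models, neural scorers/encoders) are
  intentionally out of the core; the registry accepts only the mocks.
- Adjusted (mixed-model) effect estimates are not computed; the unadjusted
  odds ratio deliberately differs from any published provider-adjusted
  estimate.
- The four-class inquiry taxonomy is consumed as input labels only; no
  classifier is provided.
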