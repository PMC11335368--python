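# promptgauge

Prompt optimization and draft-message evaluation for AI-assisted replies to
patient-portal inquiries.

Health systems increasingly let a large language model draft replies to
patient messages inside the electronic health record; a provider then edits
the draft or discards it and writes their own. `promptgauge` packages the two
quantitative workflows such a deployment needs:

1. **Prompt optimization.** Starting from a seed instruction written naïvely
   by a clinical informaticist, build a pool of paraphrases, rank them by
   **perplexity** under a likelihood model, keep the *k* least-perplexing,
   compose each with few-shot exemplar replies, generate several outputs per
   candidate, and select the candidate whose outputs are most
   **self-consistent** with ground-truth reference replies — measured as the
   mean cosine similarity between output embeddings and ground-truth
   embeddings. Perplexity of a text with token log-probabilities
   $\log p_1,\dots,\log p_T$ is
   $\mathrm{PPL} = \exp\!\big(-\tfrac1T\sum_{i=1}^T \log p_i\big) \ge 1$,
   and the self-consistency score of a candidate is
   $100 \cdot \tfrac1n \sum_{j=1}^n \cos\big(e(\hat y_j),\, e(y_{j}^{\*})\big)$
   over its $n$ generated outputs $\hat y_j$ and their reference replies
   $y_j^{*}$.
2. **Draft evaluation.** Given a corpus of message events (draft text, final
   sent text, used/seen flags, thumbs-down sentiment, study period), compute
   Damerau-Levenshtein edit distances between draft and final, normalize to a
   similarity $s = 1 - d/\max(|a|,|b|) \in [0,1]$, assign the four edit bands
   (identical $s \ge 0.9999$; nearly identical $0.9750 \le s < 0.9999$;
   similar $0.6666 \le s < 0.9750$; different $s < 0.6666$, which also
   absorbs drafts the provider discarded), and summarize usage and sentiment
   per period with a category-by-period chi-square test and unadjusted odds
   ratios.

All model access goes through three pluggable backend contracts — generator,
token-likelihood scorer, embedder — with deterministic, dependency-free mocks
shipped as the defaults, so every pipeline is reproducible offline from an
explicit seed. A synthetic-corpus generator with a logit-normal
random-intercept usage model provides realistic test fixtures with known
ground truth.

## Worked example

Optimize a prompt with the packaged demo files (mock backends throughout):

```bash
promptgauge optimize \
  --seed-prompt seed.txt --examples examples.jsonl --eval-items eval.jsonl \
  --seed 1 --out-template winner.yaml --out-audit audit.json
```

prints

```
winner seed perplexity=366.6431 mean_score=65.9
```

meaning: out of 21 candidates (20 paraphrases + the seed), the seed
instruction itself had the lowest-perplexity rank among the top-5 survivors
and its 25 mock generations scored a mean self-consistency of 65.9 on the
0–100 cosine scale. `audit.json` holds every candidate's perplexity and every
generation's similarity. (Perplexities are backend-relative: values from the
mock unigram scorer are not comparable to a neural model's.)

Compare a draft to an edited final in Python:

```python
>>> from promptgauge import compare
>>> c = compare("Your results are normal.", "Your results are normal, no action needed.")
>>> c.distance, round(c.similarity, 4), c.category.value
(18, 0.5714, 'different')
```

Eighteen single-character edits on a 42-character final give similarity
0.571, i.e. a "different" (heavily edited) draft.

Other subcommands: `promptgauge synth` (generate a synthetic corpus),
`promptgauge analyze` (usage/sentiment summary JSON with odds ratios),
`promptgauge edit-metrics` (per-event CSV plus the category-by-period table
and chi-square), `promptgauge render` (fill a template with an EHR context
and a patient message).

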