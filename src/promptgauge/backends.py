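"""Model-backend contracts and deterministic mock implementations.

The optimization pipeline needs three distinct model capabilities, mirroring
the three distinct models a production deployment would use:

* a **generator** (chat-style LLM) that produces text completions,
* a **scorer** (likelihood model) that assigns per-token log-probabilities,
  from which perplexity is computed,
* an **embedder** (encoder model such as BERT) that maps text to a
  fixed-dimension vector for cosine-similarity comparison.

Each capability is a small structural protocol so that real-model adapters can
be dropped in, but the package ships only deterministic, dependency-free mocks:
every pipeline stage is testable offline and reproducible bit-for-bit from an
explicit seed.  There is no global random state anywhere; all randomness flows
from seeds passed in requests and derived with :func:`stable_subseed`.
"""

from __future__ import annotations

import hashlib
import math
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import BackendError, ContractViolationError, InputError

__all__ = [
    "GenerationRequest",
    "TokenScoreSequence",
    "EmbeddingVector",
    "GeneratorBackend",
    "ScorerBackend",
    "EmbedderBackend",
    "MockGenerator",
    "EchoGenerator",
    "UniformScorer",
    "FrequencyTableScorer",
    "UnigramCorpusScorer",
    "HashedNgramEmbedder",
    "generate",
    "score_tokens",
    "embed",
    "cosine_similarity",
    "get_generator",
    "get_scorer",
    "get_embedder",
    "stable_subseed",
    "tokenize",
]


# ---------------------------------------------------------------------------
# seeding and tokenization helpers
# ---------------------------------------------------------------------------

def stable_subseed(seed: int, *parts: object) -> int:
    """Derive a reproducible sub-seed below 2**31 from a run seed and labels.

    Hash-based (BLAKE2b) so that sub-streams for different purposes/ids are
    decorrelated and independent of Python's per-process hash randomization.
    """
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(seed)).encode())
    for p in parts:
        h.update(b"\x1f")
        h.update(str(p).encode("utf-8"))
    return int.from_bytes(h.digest(), "big") % (2**31)


def tokenize(text: str) -> list[str]:
    """Whitespace tokens over NFC-normalized text (the mock tokenizer)."""
    return unicodedata.normalize("NFC", text).split()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationRequest:
    """A request for text generation.

    Defaults follow the production deployment being emulated: temperature 1.0
    and an output limit of 500 tokens.
    """

    prompt_text: str
    max_new_tokens: int = 500
    temperature: float = 1.0
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_new_tokens < 1:
            raise InputError("max_new_tokens must be >= 1")
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")
        if self.temperature < 0:
            raise InputError("temperature must be non-negative")


@dataclass(frozen=True)
class TokenScoreSequence:
    """Per-token natural-log conditional probabilities for a text."""

    tokens: tuple[str, ...]
    logprobs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.logprobs):
            raise ContractViolationError(
                "tokens and logprobs must have equal length"
            )
        if any(lp > 0 for lp in self.logprobs):
            raise ContractViolationError("log-probabilities must be <= 0")


@dataclass(frozen=True)
class EmbeddingVector:
    """A fixed-length, finite embedding."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.values):
            raise ContractViolationError("embedding entries must be finite")

    @property
    def dim(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def cosine_similarity(a: EmbeddingVector, b: EmbeddingVector) -> float:
    """Cosine similarity in [-1, 1]; raises on a zero-norm operand."""
    va, vb = a.as_array(), b.as_array()
    na, nb = float(np.linalg.norm(va)), float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        raise ContractViolationError("cosine similarity undefined for zero-norm embedding")
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# capability contracts
# ---------------------------------------------------------------------------

@runtime_checkable
class GeneratorBackend(Protocol):
    name: str

    def generate(self, request: GenerationRequest) -> list[str]: ...


@runtime_checkable
class ScorerBackend(Protocol):
    name: str

    def score_tokens(self, text: str) -> TokenScoreSequence: ...


@runtime_checkable
class EmbedderBackend(Protocol):
    name: str
    dim: int

    def embed(self, text: str) -> EmbeddingVector: ...


# ---------------------------------------------------------------------------
# front-door operations (validation + error wrapping)
# ---------------------------------------------------------------------------

def generate(request: GenerationRequest, backend: GeneratorBackend) -> list[str]:
    """Run a generation request; returns exactly ``request.n_samples`` strings."""
    if not request.prompt_text:
        raise InputError("prompt_text must be non-empty")
    try:
        outputs = backend.generate(request)
    except (InputError, ContractViolationError):
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise BackendError(str(exc), backend=getattr(backend, "name", "unknown")) from exc
    if len(outputs) != request.n_samples:
        raise ContractViolationError(
            f"backend {backend.name!r} returned {len(outputs)} outputs, "
            f"expected {request.n_samples}"
        )
    return outputs


def score_tokens(text: str, backend: ScorerBackend) -> TokenScoreSequence:
    """Score a text token-by-token; one logprob per token, each <= 0."""
    if not text:
        raise InputError("cannot score empty text")
    try:
        return backend.score_tokens(text)
    except (InputError, ContractViolationError):
        raise
    except Exception as exc:  # pragma: no cover
        raise BackendError(str(exc), backend=getattr(backend, "name", "unknown")) from exc


def embed(text: str, backend: EmbedderBackend) -> EmbeddingVector:
    """Embed a text into the backend's fixed-dimension space."""
    try:
        vec = backend.embed(text)
    except (InputError, ContractViolationError):
        raise
    except Exception as exc:  # pragma: no cover
        raise BackendError(str(exc), backend=getattr(backend, "name", "unknown")) from exc
    if vec.dim != backend.dim:
        raise ContractViolationError(
            f"backend {backend.name!r} returned dim {vec.dim}, declared {backend.dim}"
        )
    return vec


# ---------------------------------------------------------------------------
# mock generator
# ---------------------------------------------------------------------------

# Small synonym table used to perturb echoed prompts; chosen so paraphrases
# stay word-aligned with the source (substitutions only, plus rare adjacent
# swaps) and therefore remain "same overall meaning" stand-ins.
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "helpful": ("supportive", "useful", "constructive"),
    "respectful": ("courteous", "polite", "considerate"),
    "honest": ("truthful", "candid", "sincere"),
    "provider": ("clinician", "practitioner", "physician"),
    "answer": ("address", "respond", "reply"),
    "questions": ("inquiries", "messages", "concerns"),
    "patient": ("person", "individual", "client"),
    "safety": ("wellbeing", "security", "protection"),
    "positive": ("optimistic", "encouraging", "upbeat"),
    "formal": ("professional", "proper", "polished"),
    "relevant": ("pertinent", "related", "applicable"),
    "maintain": ("keep", "preserve", "uphold"),
}
_FILLERS = ("kindly", "please", "carefully", "promptly", "thoughtfully")


class MockGenerator:
    """Seeded template-echo generator with controlled token-level noise.

    Echoes the prompt's whitespace tokens, substituting a temperature-scaled
    fraction with synonyms (or deterministic filler words), occasionally
    swapping adjacent tokens, and truncating to ``max_new_tokens``.  At
    temperature 0 it is a pure echo.  Output is a pure function of
    (prompt_text, seed, sample index).
    """

    name = "mock"

    #: per-token substitution probability at temperature 1
    noise_rate = 0.15
    #: per-position adjacent-swap probability at temperature 1
    swap_rate = 0.03

    def generate(self, request: GenerationRequest) -> list[str]:
        base = tokenize(request.prompt_text)
        if not base:
            raise InputError("prompt_text has no tokens")
        outputs: list[str] = []
        for i in range(request.n_samples):
            rng = np.random.default_rng(
                stable_subseed(request.seed, "mockgen", i, request.prompt_text)
            )
            toks = list(base)
            t = request.temperature
            if t > 0:
                p_sub = min(0.5, self.noise_rate * t)
                for j, tok in enumerate(toks):
                    if rng.random() < p_sub:
                        key = tok.lower().strip(".,;:")
                        choices = _SYNONYMS.get(key)
                        if choices is None:
                            choices = _FILLERS
                        toks[j] = choices[int(rng.integers(len(choices)))]
                p_swap = min(0.25, self.swap_rate * t)
                j = 0
                while j < len(toks) - 1:
                    if rng.random() < p_swap:
                        toks[j], toks[j + 1] = toks[j + 1], toks[j]
                        j += 2
                    else:
                        j += 1
            outputs.append(" ".join(toks[: request.max_new_tokens]))
        return outputs


class EchoGenerator:
    """Returns the prompt verbatim (truncated); handy degenerate stub."""

    name = "echo"

    def generate(self, request: GenerationRequest) -> list[str]:
        toks = tokenize(request.prompt_text)
        if not toks:
            raise InputError("prompt_text has no tokens")
        out = " ".join(toks[: request.max_new_tokens])
        return [out] * request.n_samples


# ---------------------------------------------------------------------------
# mock scorers
# ---------------------------------------------------------------------------

class UniformScorer:
    """Assigns the same probability ``p`` to every token. Perplexity = 1/p."""

    def __init__(self, p: float = 0.5):
        if not (0 < p <= 1):
            raise InputError("p must be in (0, 1]")
        self.p = p
        self.name = f"uniform(p={p})"

    def score_tokens(self, text: str) -> TokenScoreSequence:
        toks = tuple(tokenize(text))
        if not toks:
            raise InputError("cannot score empty text")
        lp = math.log(self.p)
        return TokenScoreSequence(tokens=toks, logprobs=(lp,) * len(toks))


class FrequencyTableScorer:
    """Unigram scorer over an explicit frequency table: P(w) = freq_w / total.

    Intended for tests where per-token probabilities must be hand-computable;
    unknown tokens are an error rather than being silently smoothed.
    """

    def __init__(self, frequencies: dict[str, float]):
        if not frequencies or any(f <= 0 for f in frequencies.values()):
            raise InputError("frequencies must be positive")
        self.frequencies = dict(frequencies)
        self.total = float(sum(frequencies.values()))
        self.name = "freq-table"

    def score_tokens(self, text: str) -> TokenScoreSequence:
        toks = tuple(tokenize(text))
        if not toks:
            raise InputError("cannot score empty text")
        lps = []
        for t in toks:
            if t not in self.frequencies:
                raise InputError(f"token {t!r} not in frequency table")
            lps.append(math.log(self.frequencies[t] / self.total))
        return TokenScoreSequence(tokens=toks, logprobs=tuple(lps))


class UnigramCorpusScorer:
    """Default mock likelihood model: add-one-smoothed unigram frequencies
    estimated from a small packaged text corpus.

    P(w) = (count(w) + 1) / (N + V + 1) where N is the corpus token count and
    V the vocabulary size; every probability is strictly below 1, so all
    logprobs are negative and perplexity is > 1.  Common words score higher
    than rare or unseen ones, which is all the perplexity ranking needs.
    """

    name = "mock"

    def __init__(self, corpus_text: str | None = None):
        if corpus_text is None:
            corpus_text = (
                resources.files("promptgauge.data")
                .joinpath("scorer_corpus.txt")
                .read_text(encoding="utf-8")
            )
        counts: dict[str, int] = {}
        for tok in tokenize(corpus_text.lower()):
            counts[tok] = counts.get(tok, 0) + 1
        self._counts = counts
        self._n = sum(counts.values())
        self._v = len(counts)

    def logprob(self, token: str) -> float:
        c = self._counts.get(token.lower(), 0)
        return math.log((c + 1) / (self._n + self._v + 1))

    def score_tokens(self, text: str) -> TokenScoreSequence:
        toks = tuple(tokenize(text))
        if not toks:
            raise InputError("cannot score empty text")
        return TokenScoreSequence(
            tokens=toks, logprobs=tuple(self.logprob(t) for t in toks)
        )


# ---------------------------------------------------------------------------
# mock embedder
# ---------------------------------------------------------------------------

class HashedNgramEmbedder:
    """Hashed character-3-gram count vector, L2-normalized.

    Text is NFC-normalized and wrapped in boundary markers; each character
    trigram is hashed (BLAKE2b, stable across processes) into one of ``dim``
    buckets.  Deterministic, order-sensitive, and cheap — a stand-in for a
    sentence encoder that still makes "similar text" geometrically close.
    Empty text embeds to the zero vector.
    """

    name = "mock"

    def __init__(self, dim: int = 256):
        if dim < 1:
            raise InputError("dim must be >= 1")
        self.dim = dim

    def _bucket(self, ngram: str) -> int:
        h = hashlib.blake2b(ngram.encode("utf-8"), digest_size=4)
        return int.from_bytes(h.digest(), "big") % self.dim

    def embed(self, text: str) -> EmbeddingVector:
        v = np.zeros(self.dim, dtype=float)
        norm = unicodedata.normalize("NFC", text)
        if norm:
            padded = f"\x02{norm}\x03"
            for i in range(len(padded) - 2):
                v[self._bucket(padded[i : i + 3])] += 1.0
            n = np.linalg.norm(v)
            if n > 0:
                v /= n
        return EmbeddingVector(values=tuple(v.tolist()))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_GENERATORS = {"mock": MockGenerator, "echo": EchoGenerator}
_SCORERS = {"mock": UnigramCorpusScorer}
_EMBEDDERS = {"mock": HashedNgramEmbedder}


def get_generator(name: str = "mock") -> GeneratorBackend:
    try:
        return _GENERATORS[name]()
    except KeyError:
        raise InputError(f"unknown generator backend {name!r}") from None


def get_scorer(name: str = "mock") -> ScorerBackend:
    try:
        return _SCORERS[name]()
    except KeyError:
        raise InputError(f"unknown scorer backend {name!r}") from None


def get_embedder(name: str = "mock") -> EmbedderBackend:
    try:
        return _EMBEDDERS[name]()
    except KeyError:
        raise InputError(f"unknown embedder backend {name!r}") from None
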