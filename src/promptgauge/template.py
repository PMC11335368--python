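"""Templated prompt format: instruction text with a user-message placeholder,
bracketed EHR-field slots, and ‖-delimited few-shot example blocks.

The format emulates an EHR template mechanism: named slots such as ``[name]``
or ``[known allergies]`` are filled from a per-message context record pulled
from the chart, the literal ``<User Message>`` placeholder marks where the
patient's inquiry is inserted, and few-shot exemplar replies are serialized as
blocks separated by the ``‖`` character so the model can imitate them.

All text is NFC-normalized at parse time so token counts and edit distances
downstream are stable across Unicode representations.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .backends import ScorerBackend, score_tokens
from .errors import FormatError, InputError, RenderError

logger = logging.getLogger(__name__)

__all__ = [
    "USER_MESSAGE_PLACEHOLDER",
    "EXAMPLE_DELIMITER",
    "PromptTemplate",
    "FewShotExample",
    "parse_template",
    "serialize_template",
    "load_template_file",
    "render",
    "estimate_tokens",
    "default_template",
]

USER_MESSAGE_PLACEHOLDER = "<User Message>"
EXAMPLE_DELIMITER = "‖"  # ‖

_SLOT_RE = re.compile(r"\[([^\[\]]+)\]")


@dataclass(frozen=True)
class FewShotExample:
    """One exemplar (patient message, desired reply) pair."""

    user_message: str
    exemplar_response: str

    def __post_init__(self) -> None:
        if not self.user_message or not self.exemplar_response:
            raise InputError("few-shot example fields must be non-empty")


@dataclass(frozen=True)
class PromptTemplate:
    """A parsed prompt template.

    ``instruction`` retains the placeholder and ``[slot]`` markers verbatim;
    ``slots`` is the ordered set of slot names extracted from it.
    """

    instruction: str
    slots: tuple[str, ...] = field(default=())
    example_position: str = "before_message"  # or "end"

    def __post_init__(self) -> None:
        if self.example_position not in ("before_message", "end"):
            raise InputError(
                f"example_position must be 'before_message' or 'end', "
                f"got {self.example_position!r}"
            )


def _check_brackets(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "[":
            depth += 1
            if depth > 1:
                raise FormatError(f"nested '[' at position {i}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ']' at position {i}")
    if depth != 0:
        raise FormatError("unbalanced '[' (missing closing bracket)")


def parse_template(text: str) -> PromptTemplate:
    """Parse an instruction text into a :class:`PromptTemplate`.

    Requires exactly one user-message placeholder and balanced, non-nested
    brackets; slot names are the bracketed tokens in order of first
    appearance.
    """
    if not text:
        raise InputError("template text must be non-empty")
    text = unicodedata.normalize("NFC", text).strip()
    n_placeholders = text.count(USER_MESSAGE_PLACEHOLDER)
    if n_placeholders == 0:
        raise FormatError(
            f"template must contain the placeholder {USER_MESSAGE_PLACEHOLDER!r}"
        )
    if n_placeholders > 1:
        raise FormatError(
            f"template contains {n_placeholders} user-message placeholders; "
            "exactly one is required"
        )
    _check_brackets(text)
    slots: list[str] = []
    for name in _SLOT_RE.findall(text):
        if name not in slots:
            slots.append(name)
    return PromptTemplate(instruction=text, slots=tuple(slots))


def serialize_template(template: PromptTemplate) -> str:
    """Inverse of :func:`parse_template` (slots are re-derived on parse)."""
    return template.instruction


def load_template_file(path: str | Path) -> PromptTemplate:
    """Load a template from YAML (key ``instruction``) or plain text.

    A YAML mapping with an ``instruction`` key is the native format; any other
    content is treated as a plain-text instruction.
    """
    raw = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError:
        doc = None
    if isinstance(doc, dict) and "instruction" in doc:
        tmpl = parse_template(str(doc["instruction"]))
        pos = doc.get("example_position", "before_message")
        return PromptTemplate(
            instruction=tmpl.instruction, slots=tmpl.slots, example_position=pos
        )
    return parse_template(raw)


def _render_examples(examples: Sequence[FewShotExample]) -> str:
    blocks = [
        f"{EXAMPLE_DELIMITER} Patient: {ex.user_message}\n"
        f"Response: {ex.exemplar_response}"
        for ex in examples
    ]
    return "\n".join(blocks)


def render(
    template: PromptTemplate,
    context: Mapping[str, str],
    user_message: str,
    examples: Sequence[FewShotExample] = (),
    optional_slots: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Render a template into the final prompt string.

    Every slot is substituted inside its brackets from ``context`` (missing
    non-optional slots raise :class:`RenderError` listing all missing names);
    the user message replaces the placeholder, with the ‖-delimited example
    blocks inserted immediately before it (or appended at the end, per the
    template's ``example_position``).  Output is byte-deterministic.
    """
    if not user_message:
        raise InputError("user_message must be non-empty")
    missing = [
        s for s in template.slots if s not in context and s not in optional_slots
    ]
    if missing:
        raise RenderError(
            "context is missing required slots: " + ", ".join(repr(m) for m in missing),
            missing=missing,
        )
    unknown = set(context) - set(template.slots)
    if unknown:
        logger.warning("context keys not in template ignored: %s", sorted(unknown))

    def _sub(m: re.Match[str]) -> str:
        name = m.group(1)
        if name in context:
            return f"[{context[name]}]"
        return m.group(0)  # optional slot left as marker

    text = _SLOT_RE.sub(_sub, template.instruction)
    blocks = _render_examples(examples) if examples else ""
    if template.example_position == "before_message" and blocks:
        insertion = f"{blocks}\n{user_message}"
    else:
        insertion = user_message
    text = text.replace(USER_MESSAGE_PLACEHOLDER, insertion)
    if template.example_position == "end" and blocks:
        text = f"{text}\n{blocks}"
    return text


def estimate_tokens(text: str, scorer: ScorerBackend | None = None) -> int:
    """Token count under the scorer's tokenizer, or whitespace tokens if none.

    Monotone non-decreasing under whitespace concatenation.
    """
    if not text or not text.split():
        return 0
    if scorer is not None:
        return len(score_tokens(text, scorer).tokens)
    return len(unicodedata.normalize("NFC", text).split())


def default_template() -> PromptTemplate:
    """The packaged production-style default template."""
    from importlib import resources

    raw = (
        resources.files("promptgauge.data")
        .joinpath("default_template.txt")
        .read_text(encoding="utf-8")
    )
    return parse_template(raw)
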