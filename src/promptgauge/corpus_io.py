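"""File formats and run configuration.

Corpora are JSONL (one :class:`~promptgauge.analytics.MessageEvent` per
line, UTF-8, field names matching the dataclass); few-shot examples and
evaluation items are JSONL too; templates and run configs are YAML.
Malformed lines are reported with their line numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .analytics import MessageEvent
from .errors import FormatError, InputError
from .optimizer import EvalItem, OptimizationConfig
from .template import FewShotExample

__all__ = [
    "read_corpus",
    "write_corpus",
    "load_examples",
    "load_eval_items",
    "RunConfig",
    "load_run_config",
    "file_digest",
]

_EVENT_FIELDS = {f.name for f in dataclasses.fields(MessageEvent)}


def _event_from_obj(obj: dict, lineno: int) -> MessageEvent:
    if not isinstance(obj, dict):
        raise FormatError(f"line {lineno}: expected a JSON object")
    unknown = set(obj) - _EVENT_FIELDS
    if unknown:
        raise FormatError(f"line {lineno}: unknown fields {sorted(unknown)}")
    try:
        return MessageEvent(**obj)
    except (TypeError, InputError) as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path) -> list[MessageEvent]:
    """Read a JSONL corpus; every line must parse and validate."""
    events: list[MessageEvent] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            events.append(_event_from_obj(obj, lineno))
    if not events:
        raise InputError(f"corpus file {path} contains no events")
    return events


def write_corpus(events: Sequence[MessageEvent], path: str | Path) -> None:
    """Write events as JSONL, omitting unset optional fields."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            obj = {k: v for k, v in dataclasses.asdict(e).items() if v is not None}
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def load_examples(path: str | Path) -> list[FewShotExample]:
    """Few-shot examples from JSONL ({user_message, exemplar_response})."""
    out: list[FewShotExample] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(FewShotExample(**obj))
            except (json.JSONDecodeError, TypeError, InputError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    if not out:
        raise InputError(f"examples file {path} is empty")
    return out


def load_eval_items(path: str | Path) -> list[EvalItem]:
    """Evaluation items from JSONL ({item_id, user_message,
    ground_truth_response, ehr_context?})."""
    out: list[EvalItem] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(EvalItem(**obj))
            except (json.JSONDecodeError, TypeError, InputError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    if not out:
        raise InputError(f"eval-items file {path} is empty")
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration; schema-validated, unknown keys rejected."""

    generator: str = "mock"
    scorer: str = "mock"
    embedder: str = "mock"
    variant: str = "osa"
    seed: int = 0
    optimization: OptimizationConfig = dataclasses.field(
        default_factory=OptimizationConfig
    )

    def __post_init__(self) -> None:
        if self.variant not in ("osa", "unrestricted_dl"):
            raise InputError(f"variant must be 'osa' or 'unrestricted_dl', got {self.variant!r}")


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise FormatError("run config must be a YAML mapping")
    known = {"generator", "scorer", "embedder", "variant", "seed", "optimization"}
    unknown = set(doc) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    opt = doc.pop("optimization", {})
    if not isinstance(opt, dict):
        raise FormatError("'optimization' must be a mapping")
    opt_known = {f.name for f in dataclasses.fields(OptimizationConfig)}
    opt_unknown = set(opt) - opt_known
    if opt_unknown:
        raise InputError(f"unknown optimization keys: {sorted(opt_unknown)}")
    try:
        return RunConfig(optimization=OptimizationConfig(**opt), **doc)
    except TypeError as exc:
        raise InputError(str(exc)) from exc


def file_digest(path: str | Path) -> str:
    """Short SHA-256 digest of a file, for reproducibility logging."""
    h = hashlib.sha256(Path(path).read_bytes())
    return h.hexdigest()[:16]
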