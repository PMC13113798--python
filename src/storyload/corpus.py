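"""Corpus and outcome-table I/O.

A stimulus corpus is a directory of UTF-8 plain-text narratives plus a CSV
manifest (``id,file,role,sentence_count_override``). Produced-IU outcomes
live in a second CSV (``id,role,iu_pre,iu_post,iu_post1,iu_post2``). Both
loaders validate the role-specific invariants up front so that downstream
modules can assume clean records.

Roles
-----
``treated``
    Stimulus trained in a therapy session; retold pre and immediately post
    within the same session (``iu_pre``/``iu_post``).
``evaluation``
    Never-trained stimulus retold at three timepoints — pre-treatment,
    immediately post-treatment (Post1) and at delayed follow-up (Post2) —
    to probe generalization and maintenance (``iu_pre``/``iu_post1``/``iu_post2``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import CorpusLoadError, ValidationError

ROLES = ("treated", "evaluation")

MANIFEST_COLUMNS = ("id", "file", "role")
OUTCOME_COLUMNS = ("id", "role", "iu_pre", "iu_post", "iu_post1", "iu_post2")


def _normalize_text(raw: str) -> str:
    """Strip a BOM and normalize CRLF / lone CR line endings to LF."""
    if raw.startswith("\ufeff"):
        raw = raw[1:]
    return raw.replace("\r\n", "\n").replace("\r", "\n")


@dataclass(frozen=True)
class StimulusRecord:
    """One narrative stimulus: its text, role and optional manual sentence count.

    ``sentence_count_override`` is the sanctioned correction path for the
    rule-based sentence splitter (e.g. abbreviation-induced over-splits):
    when set, the effective sentence count is the override while the
    automatic split is retained for per-sentence analyses.
    """

    stimulus_id: str
    text: str
    role: str
    sentence_count_override: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.stimulus_id:
            raise ValidationError("stimulus_id must be nonempty")
        if not self.text.strip():
            raise ValidationError(f"stimulus {self.stimulus_id!r}: text is empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"stimulus {self.stimulus_id!r}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )
        if self.sentence_count_override is not None and self.sentence_count_override < 1:
            raise ValidationError(
                f"stimulus {self.stimulus_id!r}: sentence_count_override must be >= 1"
            )


@dataclass
class StimulusCorpus:
    """Ordered collection of stimuli; order follows the manifest row order."""

    records: list[StimulusRecord]
    source_manifest: str = ""

    def __post_init__(self) -> None:
        ids = [r.stimulus_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate stimulus ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.stimulus_id for r in self.records]


@dataclass(frozen=True)
class OutcomeRecord:
    """Produced Information Unit counts for one stimulus across timepoints."""

    stimulus_id: str
    role: str
    iu_pre: int
    iu_post: Optional[int] = None
    iu_post1: Optional[int] = None
    iu_post2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"outcome {self.stimulus_id!r}: unknown role {self.role!r}"
            )
        for name in ("iu_pre", "iu_post", "iu_post1", "iu_post2"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(
                    f"outcome {self.stimulus_id!r}: {name} must be >= 0, got {value}"
                )
        if self.role == "treated" and self.iu_post is None:
            raise ValidationError(
                f"outcome {self.stimulus_id!r}: treated records require iu_post"
            )
        if self.role == "evaluation" and (self.iu_post1 is None or self.iu_post2 is None):
            raise ValidationError(
                f"outcome {self.stimulus_id!r}: evaluation records require "
                "iu_post1 and iu_post2"
            )


def _read_rows(path: Path, required: Iterable[str]) -> list[dict]:
    try:
        with open(path, newline="", encoding="utf-8-sig") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in required if c not in header]
            if missing:
                raise ValidationError(
                    f"{path}: missing required columns {missing}; found {header}"
                )
            return list(reader)
    except OSError as exc:
        raise CorpusLoadError(f"cannot read {path}: {exc}") from exc


def load_corpus(manifest_path: str | Path) -> StimulusCorpus:
    """Load a stimulus corpus from its CSV manifest.

    The manifest has columns ``id,file,role`` and optionally
    ``sentence_count_override``; ``file`` paths are resolved relative to the
    manifest's directory. Text files are read as UTF-8, BOM-stripped, and
    line-ending-normalized so feature counts never depend on the platform.
    """
    manifest_path = Path(manifest_path)
    rows = _read_rows(manifest_path, MANIFEST_COLUMNS)
    if not rows:
        raise ValidationError(f"{manifest_path}: no stimuli in manifest")
    records = []
    for row in rows:
        sid = (row.get("id") or "").strip()
        rel = (row.get("file") or "").strip()
        text_path = Path(rel)
        if not text_path.is_absolute():
            text_path = manifest_path.parent / text_path
        try:
            raw = text_path.read_text(encoding="utf-8")
        except OSError as exc:
            raise CorpusLoadError(
                f"stimulus {sid!r}: cannot read text file {text_path}: {exc}"
            ) from exc
        override_raw = (row.get("sentence_count_override") or "").strip()
        override = int(override_raw) if override_raw else None
        records.append(
            StimulusRecord(
                stimulus_id=sid,
                text=_normalize_text(raw),
                role=(row.get("role") or "").strip(),
                sentence_count_override=override,
            )
        )
    return StimulusCorpus(records=records, source_manifest=str(manifest_path))


def write_corpus(corpus: StimulusCorpus, out_dir: str | Path) -> Path:
    """Write texts plus manifest under ``out_dir``; returns the manifest path.

    The written layout round-trips through :func:`load_corpus` with
    field-by-field equality.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "file", "role", "sentence_count_override"])
        for rec in corpus:
            fname = f"{rec.stimulus_id}.txt"
            (out_dir / fname).write_text(rec.text, encoding="utf-8")
            writer.writerow(
                [
                    rec.stimulus_id,
                    fname,
                    rec.role,
                    "" if rec.sentence_count_override is None else rec.sentence_count_override,
                ]
            )
    return manifest_path


def _parse_count(row: dict, column: str) -> Optional[int]:
    raw = (row.get(column) or "").strip()
    if not raw:
        return None
    try:
        return int(raw)
    except ValueError as exc:
        raise ValidationError(
            f"outcome {row.get('id')!r}: {column} must be an integer, got {raw!r}"
        ) from exc


def load_outcomes(outcomes_path: str | Path) -> list[OutcomeRecord]:
    """Load produced-IU outcome records, enforcing role-specific timepoints."""
    rows = _read_rows(Path(outcomes_path), ("id", "role", "iu_pre"))
    records = []
    for row in rows:
        pre = _parse_count(row, "iu_pre")
        if pre is None:
            raise ValidationError(f"outcome {row.get('id')!r}: iu_pre is required")
        records.append(
            OutcomeRecord(
                stimulus_id=(row.get("id") or "").strip(),
                role=(row.get("role") or "").strip(),
                iu_pre=pre,
                iu_post=_parse_count(row, "iu_post"),
                iu_post1=_parse_count(row, "iu_post1"),
                iu_post2=_parse_count(row, "iu_post2"),
            )
        )
    ids = [r.stimulus_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate outcome ids: {', '.join(dupes)}")
    return records


def write_outcomes(records: list[OutcomeRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OUTCOME_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.stimulus_id,
                    rec.role,
                    rec.iu_pre,
                    "" if rec.iu_post is None else rec.iu_post,
                    "" if rec.iu_post1 is None else rec.iu_post1,
                    "" if rec.iu_post2 is None else rec.iu_post2,
                ]
            )
    return path


def corpus_provenance(corpus: StimulusCorpus) -> str:
    """JSON echo of a validated corpus (ids, roles, overrides) for logging."""
    return json.dumps(
        {
            "source_manifest": corpus.source_manifest,
            "n_stimuli": len(corpus),
            "records": [
                {
                    "id": r.stimulus_id,
                    "role": r.role,
                    "sentence_count_override": r.sentence_count_override,
                    "n_chars": len(r.text),
                }
                for r in corpus
            ],
        },
        indent=2,
    )
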