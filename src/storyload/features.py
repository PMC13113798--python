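"""Rule-based structural feature extraction.

Four surface features summarize the structural demands a narrative places
on a listener:

* **sentence_count** — number of sentences, from a punctuation-based
  splitter with an optional manual override for known failure modes
  (abbreviations, functional clause boundaries).
* **avg_sentence_length** — words per sentence (total word count divided by
  the effective sentence count), a syntactic-load proxy.
* **complex_ratio** — fraction of sentences containing at least one
  subordinating conjunction (because, although, when, if, since, though,
  unless, while), a clause-embedding proxy.
* **estimated_ius** — commas + occurrences of "and" + occurrences of
  "but": a surface proxy for the informational density of the *written*
  stimulus. Not comparable to produced Information Units scored from
  spoken retellings.

All operators are deterministic string rules: no tagger, no parser, no
model. Keyword matching defaults to case-insensitive whole-word matches;
a ``substring`` mode reproduces naive ``str.count``-style matching (where
"band" contains "and") for parity with simpler pipelines.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional

import yaml

from .corpus import StimulusRecord
from .errors import SegmentationError, ValidationError

#: Default subordinating conjunctions flagging a sentence as complex.
DEFAULT_SUBORDINATORS = frozenset(
    {"because", "although", "when", "if", "since", "though", "unless", "while"}
)

IU_MATCH_MODES = ("word_boundary", "substring")

# Split after a run of sentence-final punctuation followed by whitespace;
# terminators stay attached to the preceding fragment.
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable matching rules for the keyword-based features.

    ``iu_match_mode`` governs how ``and``/``but`` and the subordinators are
    located: ``word_boundary`` (default) requires whole-word matches;
    ``substring`` counts raw substring occurrences.
    """

    subordinators: frozenset[str] = DEFAULT_SUBORDINATORS
    iu_match_mode: str = "word_boundary"
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if not self.subordinators:
            raise ValidationError("subordinator set must be nonempty")
        if self.iu_match_mode not in IU_MATCH_MODES:
            raise ValidationError(
                f"iu_match_mode must be one of {IU_MATCH_MODES}, "
                f"got {self.iu_match_mode!r}"
            )
        object.__setattr__(self, "subordinators", frozenset(w.lower() for w in self.subordinators))

    def to_dict(self) -> dict:
        return {
            "subordinators": sorted(self.subordinators),
            "iu_match_mode": self.iu_match_mode,
            "case_insensitive": self.case_insensitive,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureConfig":
        kwargs = dict(data)
        if "subordinators" in kwargs:
            kwargs["subordinators"] = frozenset(kwargs["subordinators"])
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass(frozen=True)
class SentenceSegmentation:
    """Auto-split sentences plus the effective count used for ratios.

    When a manual override is present the effective count follows the
    override (provenance ``override``) while ``sentences`` keeps the
    automatic split for per-sentence keyword flags.
    """

    sentences: tuple[str, ...]
    provenance: str  # "auto" | "override"
    effective_count: int


@dataclass(frozen=True)
class FeatureVector:
    """The four raw structural features plus word count for one stimulus."""

    stimulus_id: str
    sentence_count: int
    word_count: int
    avg_sentence_length: float
    complex_ratio: float
    estimated_ius: int


def segment_sentences(record: StimulusRecord) -> SentenceSegmentation:
    """Split text into sentences on runs of ``. ! ?`` followed by whitespace.

    Empty fragments are discarded. Raises :class:`SegmentationError` if no
    sentence survives.
    """
    fragments = [frag.strip() for frag in _SENTENCE_SPLIT.split(record.text)]
    sentences = tuple(frag for frag in fragments if frag)
    if not sentences:
        raise SegmentationError(
            f"stimulus {record.stimulus_id!r}: no sentences after segmentation"
        )
    if record.sentence_count_override is not None:
        return SentenceSegmentation(
            sentences=sentences,
            provenance="override",
            effective_count=record.sentence_count_override,
        )
    return SentenceSegmentation(
        sentences=sentences, provenance="auto", effective_count=len(sentences)
    )


def count_words(text: str) -> int:
    """Whitespace-delimited token count; punctuation stays attached to tokens."""
    return len(text.split())


def _keyword_pattern(word: str, cfg: FeatureConfig) -> re.Pattern:
    flags = re.IGNORECASE if cfg.case_insensitive else 0
    if cfg.iu_match_mode == "word_boundary":
        return re.compile(rf"\b{re.escape(word)}\b", flags)
    return re.compile(re.escape(word), flags)


def _count_keyword(text: str, word: str, cfg: FeatureConfig) -> int:
    return len(_keyword_pattern(word, cfg).findall(text))


def contains_subordinator(sentence: str, cfg: FeatureConfig) -> bool:
    return any(_keyword_pattern(w, cfg).search(sentence) for w in cfg.subordinators)


def complex_sentence_ratio(seg: SentenceSegmentation, cfg: Optional[FeatureConfig] = None) -> float:
    """Fraction of sentences containing at least one subordinating conjunction.

    The numerator is counted over the automatic split (a sentence with
    several subordinators counts once); the denominator is the effective
    sentence count, so a manual override changes the ratio's scale.
    """
    cfg = cfg or FeatureConfig()
    if seg.effective_count < 1:
        raise SegmentationError("complex ratio undefined for zero sentences")
    numerator = sum(1 for s in seg.sentences if contains_subordinator(s, cfg))
    if numerator > seg.effective_count:
        warnings.warn(
            "more subordinator-bearing sentences than the effective sentence "
            f"count ({numerator} > {seg.effective_count}); clamping numerator",
            stacklevel=2,
        )
        numerator = seg.effective_count
    return numerator / seg.effective_count


def estimated_ius(text: str, cfg: Optional[FeatureConfig] = None) -> int:
    """Commas + "and" occurrences + "but" occurrences.

    Only the ASCII comma (U+002C) counts; semicolons and dashes do not.
    """
    cfg = cfg or FeatureConfig()
    return (
        text.count(",")
        + _count_keyword(text, "and", cfg)
        + _count_keyword(text, "but", cfg)
    )


def extract_features(record: StimulusRecord, cfg: Optional[FeatureConfig] = None) -> FeatureVector:
    """Compose the four operators into one feature vector.

    ``avg_sentence_length`` is kept at full precision (word_count divided by
    the effective sentence count); any rounding is a display concern.
    """
    cfg = cfg or FeatureConfig()
    seg = segment_sentences(record)
    words = count_words(record.text)
    return FeatureVector(
        stimulus_id=record.stimulus_id,
        sentence_count=seg.effective_count,
        word_count=words,
        avg_sentence_length=words / seg.effective_count,
        complex_ratio=complex_sentence_ratio(seg, cfg),
        estimated_ius=estimated_ius(record.text, cfg),
    )
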