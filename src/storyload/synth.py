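"""Synthetic narrative stimuli with exact target features, plus packaged
reference tables.

The generator is the inverse of the feature extractors: given target
sentence count, word count, complex-sentence numerator and estimated-IU
count, it builds a filler-word text that hits all four targets *by
construction* — counts are tracked while the text is assembled, not fitted
afterwards. Texts are word salad, not stories: they exercise the counting
rules, not narrative semantics.

Guarantees (under the default :class:`~storyload.features.FeatureConfig`,
and identically in ``substring`` mode — the filler vocabulary contains no
keyword as a substring):

* auto sentence split yields exactly ``target_sentence_count`` sentences;
* whitespace token count equals ``target_word_count``;
* exactly ``target_complex_numerator`` sentences contain a subordinator;
* commas + "and" + "but" events equal ``target_ius``;
* generation is deterministic given ``seed``.

The module also packages the study's reference tables (per-stimulus raw
features with printed composites/blocks, per-stimulus IU gains, and the
three evaluation-stimulus IU trajectories) as CSV resources, since the
original narrative texts — adaptations of the Discourse Comprehension
Test stories — are not redistributable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import StimulusCorpus, StimulusRecord
from .errors import UnachievableSpecError, ValidationError
from .features import FeatureVector
from .outcomes import GainRecord

# Closed filler vocabulary. No entry contains (as a substring) a comma, a
# sentence terminator, "and", "but", or any default subordinator — so
# word_boundary and substring matching agree on every generated text.
FILLER_WORDS = (
    "the", "dog", "ran", "to", "park", "cat", "sat", "on", "mat",
    "old", "man", "saw", "red", "car", "she", "he", "they", "walked",
    "home", "store", "big", "small", "tree", "near", "road", "slowly",
)

IU_WORDS = ("and", "but")

DEFAULT_SUBORDINATOR_CYCLE = (
    "because", "although", "when", "if", "since", "though", "unless", "while"
)


@dataclass(frozen=True)
class SynthSpec:
    """Target feature values for one generated stimulus."""

    target_sentence_count: int
    target_word_count: int
    target_complex_numerator: int
    target_ius: int
    seed: int = 0
    stimulus_id: str = "synth"
    role: str = "treated"

    def validate(self) -> None:
        s, w, c, k = (
            self.target_sentence_count,
            self.target_word_count,
            self.target_complex_numerator,
            self.target_ius,
        )
        if s < 1:
            raise UnachievableSpecError(f"{self.stimulus_id}: need >= 1 sentence, got {s}")
        if k < 0:
            raise UnachievableSpecError(f"{self.stimulus_id}: target_ius must be >= 0")
        if not 0 <= c <= s:
            raise UnachievableSpecError(
                f"{self.stimulus_id}: complex numerator {c} outside [0, {s}]"
            )
        if w < s:
            raise UnachievableSpecError(
                f"{self.stimulus_id}: {w} words cannot fill {s} sentences "
                "(each sentence needs >= 1 word)"
            )
        if w < s + 2 * c:
            raise UnachievableSpecError(
                f"{self.stimulus_id}: {w} words too few for {c} complex "
                f"sentences (each needs >= 3 words): require >= {s + 2 * c}"
            )


def generate_stimulus(spec: SynthSpec) -> StimulusRecord:
    """Build a text whose extracted features equal the spec targets exactly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s, w, c, k = (
        spec.target_sentence_count,
        spec.target_word_count,
        spec.target_complex_numerator,
        spec.target_ius,
    )

    # word budget: 1 word/sentence minimum, 3 for complex; spares at random
    complex_idx = set(rng.choice(s, size=c, replace=False).tolist())
    lengths = np.array([3 if i in complex_idx else 1 for i in range(s)])
    for _ in range(w - int(lengths.sum())):
        lengths[rng.integers(0, s)] += 1

    sentences: list[list[str]] = []
    sub_positions: set[tuple[int, int]] = set()  # (sentence, word) holding a subordinator
    for i in range(s):
        n = int(lengths[i])
        words = [str(rng.choice(FILLER_WORDS)) for _ in range(n)]
        if i in complex_idx:
            pos = int(rng.integers(1, n - 1))  # interior: filler on both sides
            words[pos] = str(rng.choice(DEFAULT_SUBORDINATOR_CYCLE))
            sub_positions.add((i, pos))
        sentences.append(words)

    # IU events: replace spare fillers with and/but, rest become commas
    candidates = [
        (i, j)
        for i, words in enumerate(sentences)
        for j in range(1, len(words) - 1)
        if (i, j) not in sub_positions
    ]
    rng.shuffle(candidates)
    n_words = int(rng.integers(0, min(k, len(candidates)) + 1))
    for i, j in candidates[:n_words]:
        sentences[i][j] = str(rng.choice(IU_WORDS))

    n_commas = k - n_words
    comma_hosts = [
        (i, j) for i, words in enumerate(sentences) for j in range(len(words) - 1)
    ]
    rng.shuffle(comma_hosts)
    for t in range(n_commas):
        if comma_hosts:
            i, j = comma_hosts[t % len(comma_hosts)]
            sentences[i][j] += ","
        else:  # one-word sentences only: comma precedes the final period
            i = t % s
            sentences[i][-1] += ","

    rendered = []
    for words in sentences:
        words[0] = words[0][0].upper() + words[0][1:]
        rendered.append(" ".join(words) + ".")
    return StimulusRecord(
        stimulus_id=spec.stimulus_id,
        text=" ".join(rendered),
        role=spec.role,
        sentence_count_override=None,
    )


#: Feature ranges mirroring the profiled study corpus (12 short narratives).
DEFAULT_FEATURE_RANGES = {
    "sentence_count": (11, 16),
    "word_count": (150, 230),
    "complex_ratio": (0.10, 0.90),
    "estimated_ius": (10, 22),
}


def generate_corpus(
    n: int,
    feature_ranges: Optional[dict] = None,
    seed: int = 0,
) -> tuple[StimulusCorpus, pd.DataFrame]:
    """Generate ``n`` stimuli with features drawn uniformly from ranges.

    Returns the corpus plus its ground-truth feature table for oracle
    comparison. Requires ``n >= 3`` so downstream tertile blocks exist.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3 stimuli for tertile blocks, got {n}")
    ranges = {**DEFAULT_FEATURE_RANGES, **(feature_ranges or {})}
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for i in range(n):
        s = int(rng.integers(ranges["sentence_count"][0], ranges["sentence_count"][1] + 1))
        lo_w = max(ranges["word_count"][0], 3 * s)
        w = int(rng.integers(lo_w, max(lo_w, ranges["word_count"][1]) + 1))
        ratio = rng.uniform(*ranges["complex_ratio"])
        c = int(np.clip(round(ratio * s), 0, min(s, (w - s) // 2)))
        k = int(rng.integers(ranges["estimated_ius"][0], ranges["estimated_ius"][1] + 1))
        spec = SynthSpec(
            target_sentence_count=s,
            target_word_count=w,
            target_complex_numerator=c,
            target_ius=k,
            seed=int(rng.integers(0, 2**31 - 1)),
            stimulus_id=f"story_{i + 1:02d}",
        )
        records.append(generate_stimulus(spec))
        truth_rows.append(
            {
                "id": spec.stimulus_id,
                "sentence_count": s,
                "word_count": w,
                "avg_sentence_length": w / s,
                "complex_ratio": c / s,
                "estimated_ius": k,
            }
        )
    return StimulusCorpus(records=records), pd.DataFrame(truth_rows)


@dataclass
class FixtureSet:
    """Packaged reference tables from the profiled 12-stimulus study."""

    table1_features: pd.DataFrame
    table2_outcomes: pd.DataFrame
    trajectories: pd.DataFrame


def _read_resource(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("storyload.data") / name
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, **kwargs)


def load_fixtures() -> FixtureSet:
    """Load the packaged reference tables.

    ``printed_composite`` columns keep the published strings verbatim (the
    two tables print one stimulus at different precision); a float
    ``composite`` column is derived alongside. Evaluation-only stimuli are
    Gas, Library and Loan.
    """
    t1 = _read_resource("table1_features.csv", dtype={"printed_composite": str})
    t1["composite"] = t1["printed_composite"].astype(float)
    t2 = _read_resource("table2_outcomes.csv", dtype={"printed_composite": str})
    t2["composite"] = t2["printed_composite"].astype(float)
    traj = _read_resource("trajectories.csv")
    return FixtureSet(table1_features=t1, table2_outcomes=t2, trajectories=traj)


def table1_feature_vectors(fixtures: Optional[FixtureSet] = None) -> list[FeatureVector]:
    """Reconstruct full-precision feature vectors from the published table.

    Printed average sentence length and complex ratio are 2-decimal
    roundings; the exact values are recovered as ``word_count /
    sentence_count`` and ``round(ratio · n) / n`` (the nearest integer
    numerator over the sentence count).
    """
    fx = fixtures or load_fixtures()
    vectors = []
    for row in fx.table1_features.itertuples():
        sc = int(row.sentence_count)
        wc = int(row.word_count)
        numerator = round(float(row.complex_ratio) * sc)
        vectors.append(
            FeatureVector(
                stimulus_id=row.id,
                sentence_count=sc,
                word_count=wc,
                avg_sentence_length=wc / sc,
                complex_ratio=numerator / sc,
                estimated_ius=int(row.estimated_ius),
            )
        )
    return vectors


def fixture_roles(fixtures: Optional[FixtureSet] = None) -> dict[str, str]:
    fx = fixtures or load_fixtures()
    return dict(zip(fx.table2_outcomes["id"], fx.table2_outcomes["role"]))


def fixture_gain_records(fixtures: Optional[FixtureSet] = None) -> list[GainRecord]:
    """Published IU gains as GainRecords.

    Treated stimuli carry the published within-session gain directly (the
    raw pre/post counts appear only graphically). Evaluation records are
    rebuilt from their three-timepoint trajectories, so their gain and
    interval decomposition are derived, not copied.
    """
    fx = fixtures or load_fixtures()
    traj = fx.trajectories.set_index("id")
    records = []
    for row in fx.table2_outcomes.itertuples():
        if row.role == "evaluation":
            t = traj.loc[row.id]
            intervals = (
                int(t.iu_post1 - t.iu_pre),
                int(t.iu_post2 - t.iu_pre),
                int(t.iu_post2 - t.iu_post1),
            )
            records.append(
                GainRecord(row.id, row.role, gain=intervals[1], interval_gains=intervals)
            )
        else:
            records.append(GainRecord(row.id, row.role, gain=int(row.iu_gain)))
    return records
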