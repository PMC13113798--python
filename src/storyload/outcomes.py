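"""Produced-IU gain analysis.

Relates stimulus-level structural load to the change in Information Units
(IUs) produced in retellings. Gains are role-specific:

* treated stimuli — within-session change, ``iu_post − iu_pre``;
* evaluation-only stimuli — delayed change, ``iu_post2 − iu_pre``, with
  the interval decomposition (Post1−Pre, Post2−Pre, Post2−Post1)
  reported alongside.

The analysis is descriptive: Pearson correlations between composites and
gains for the {all, treated, evaluation} subsets, mean gains per load
block, and mean gains per condition. With a dozen stimuli from a single
participant these are directional summaries, not inferential statistics;
p-values are available behind an explicit flag and come with a small-n
warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import OutcomeRecord
from .errors import JoinError, UndefinedCorrelationError, ValidationError
from .profiling import BLOCK_LABELS, ProfileTable


@dataclass(frozen=True)
class GainRecord:
    """Per-stimulus IU gain; evaluation records carry the interval triple."""

    stimulus_id: str
    role: str
    gain: int
    interval_gains: Optional[tuple[int, int, int]] = None  # (p1-pre, p2-pre, p2-p1)


@dataclass
class AnalysisSummary:
    """Correlations and group means over the profile/gain join."""

    correlations: list[dict]  # {"subset": str, "n": int, "r": float[, "p": float]}
    block_means: dict[str, float]
    condition_means: dict[str, float]
    treated_block_means: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = {
            "correlations": self.correlations,
            "block_means": self.block_means,
            "condition_means": self.condition_means,
            "treated_block_means": self.treated_block_means,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def compute_gains(outcomes: Sequence[OutcomeRecord]) -> list[GainRecord]:
    """Derive role-specific IU gains from raw timepoint counts."""
    records = []
    for out in outcomes:
        if out.role == "treated":
            if out.iu_post is None:
                raise ValidationError(
                    f"outcome {out.stimulus_id!r}: treated gain needs iu_post"
                )
            records.append(
                GainRecord(out.stimulus_id, out.role, gain=out.iu_post - out.iu_pre)
            )
        else:
            if out.iu_post1 is None or out.iu_post2 is None:
                raise ValidationError(
                    f"outcome {out.stimulus_id!r}: evaluation gain needs "
                    "iu_post1 and iu_post2"
                )
            intervals = (
                out.iu_post1 - out.iu_pre,
                out.iu_post2 - out.iu_pre,
                out.iu_post2 - out.iu_post1,
            )
            records.append(
                GainRecord(
                    out.stimulus_id,
                    out.role,
                    gain=intervals[1],
                    interval_gains=intervals,
                )
            )
    return records


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient at full precision.

    Raises :class:`UndefinedCorrelationError` on fewer than 3 pairs or on a
    zero-variance argument rather than returning NaN.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need at least 3 pairs, got {len(x)}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def gains_frame(gains: Sequence[GainRecord]) -> pd.DataFrame:
    """Tidy per-stimulus gain table (one row per stimulus)."""
    return pd.DataFrame(
        {
            "id": [g.stimulus_id for g in gains],
            "role": [g.role for g in gains],
            "gain": [g.gain for g in gains],
            "gain_post1_pre": [
                g.interval_gains[0] if g.interval_gains else None for g in gains
            ],
            "gain_post2_pre": [
                g.interval_gains[1] if g.interval_gains else None for g in gains
            ],
            "gain_post2_post1": [
                g.interval_gains[2] if g.interval_gains else None for g in gains
            ],
        }
    )


def summarize(
    profile: ProfileTable,
    gains: Sequence[GainRecord],
    with_p_values: bool = False,
) -> AnalysisSummary:
    """Join gains onto the profile and summarize by subset, block, condition.

    Correlations are computed for the full set and for each role subset
    present in the data; a present subset too small or degenerate for a
    correlation raises rather than silently reporting NaN.
    """
    prof = profile.table.set_index("id")
    gdf = gains_frame(gains).set_index("id")
    orphans = sorted(set(gdf.index) - set(prof.index))
    if orphans:
        raise JoinError(f"gain ids missing from profile: {', '.join(orphans)}")
    joined = gdf.join(prof[["composite", "block"]], how="left")

    subsets = {
        "all": joined,
        "treated": joined[joined["role"] == "treated"],
        "evaluation": joined[joined["role"] == "evaluation"],
    }
    correlations = []
    for label, sub in subsets.items():
        if len(sub) == 0:  # role absent from this corpus: nothing to correlate
            continue
        entry = {
            "subset": label,
            "n": int(len(sub)),
            "r": pearson_r(sub["composite"], sub["gain"]),
        }
        if with_p_values:
            if len(sub) < 12:
                warnings.warn(
                    f"p-value for subset {label!r} computed from n={len(sub)}; "
                    "interpret with caution",
                    stacklevel=2,
                )
            entry["p"] = float(
                stats.pearsonr(sub["composite"], sub["gain"]).pvalue
            )
        correlations.append(entry)

    block_means = {
        b: float(joined.loc[joined["block"] == b, "gain"].mean())
        for b in BLOCK_LABELS
        if (joined["block"] == b).any()
    }
    condition_means = {
        role: float(sub["gain"].mean())
        for role, sub in (("treated", subsets["treated"]), ("evaluation", subsets["evaluation"]))
        if len(sub)
    }
    treated = subsets["treated"]
    treated_block_means = {
        b: float(treated.loc[treated["block"] == b, "gain"].mean())
        for b in BLOCK_LABELS
        if (treated["block"] == b).any()
    }
    return AnalysisSummary(
        correlations=correlations,
        block_means=block_means,
        condition_means=condition_means,
        treated_block_means=treated_block_means,
    )
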