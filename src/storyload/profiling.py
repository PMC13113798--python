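"""Corpus-level normalization, composite load scores and tertile blocks.

Each raw feature x is standardized across the corpus, z = (x − μ)/σ, with σ
the **population** standard deviation (divide by n). The Composite
Structural Load Score of a stimulus is the unweighted mean of its four
feature z-scores:

    composite = (z_sentence_count + z_complex_ratio + z_avg_length + z_ius) / 4

Composites are then rank-binned into three equal-size (±1) tertile blocks,
Low < Medium < High, with High holding the top third of scores.

Two numerical conventions matter and are deliberate:

* population σ, not the sample (n−1) estimator — the composite is a
  within-corpus standardization, not an inference about a larger stimulus
  population;
* composites are computed from full-precision features (e.g. the exact
  ratio 6/14, not its 2-decimal display value); rounding happens only in
  reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import StimulusCorpus
from .errors import DegenerateFeatureError, ValidationError
from .features import FeatureConfig, FeatureVector, extract_features

#: Feature columns entering the composite, in report order.
FEATURE_COLUMNS = ("sentence_count", "avg_sentence_length", "complex_ratio", "estimated_ius")
Z_COLUMNS = tuple(f"z_{c}" for c in FEATURE_COLUMNS)
BLOCK_LABELS = ("Low", "Medium", "High")


@dataclass
class ProfileTable:
    """Per-stimulus features, z-scores, composites and load blocks.

    ``table`` preserves the corpus row order and carries columns
    ``id, role, sentence_count, word_count, avg_sentence_length,
    complex_ratio, estimated_ius, z_* (4), composite, block`` at full
    precision. ``mu``/``sigma`` are the per-feature normalization constants.
    """

    table: pd.DataFrame
    mu: dict[str, float]
    sigma: dict[str, float]
    config: Optional[FeatureConfig] = None

    def composites(self) -> pd.Series:
        return self.table.set_index("id")["composite"]

    def blocks(self) -> pd.Series:
        return self.table.set_index("id")["block"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path=None) -> str:
        payload = {
            "mu": self.mu,
            "sigma": self.sigma,
            "sigma_convention": "population",
            "config": self.config.to_dict() if self.config else None,
            "rows": self.table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ProfileTable":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg = FeatureConfig.from_dict(payload["config"]) if payload.get("config") else None
        return cls(
            table=pd.DataFrame(payload["rows"]),
            mu=payload["mu"],
            sigma=payload["sigma"],
            config=cfg,
        )


def zscore_features(
    features: Sequence[FeatureVector],
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Standardize the four feature columns across a corpus.

    Returns ``(ztable, mu, sigma)`` with σ the population standard
    deviation. Raises :class:`DegenerateFeatureError` naming any constant
    column, for which no z-score exists.
    """
    if len(features) < 2:
        raise ValidationError("z-scores require at least 2 stimuli")
    raw = pd.DataFrame(
        {
            "id": [f.stimulus_id for f in features],
            **{c: [getattr(f, c) for f in features] for c in FEATURE_COLUMNS},
        }
    )
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    ztable = pd.DataFrame({"id": raw["id"]})
    degenerate = [c for c in FEATURE_COLUMNS if np.std(raw[c].to_numpy(float)) == 0.0]
    if degenerate:
        raise DegenerateFeatureError(
            f"constant feature column(s) {degenerate}: z-scores undefined"
        )
    for col in FEATURE_COLUMNS:
        x = raw[col].to_numpy(dtype=float)
        mu[col] = float(x.mean())
        sigma[col] = float(x.std())  # population (divide by n)
        ztable[f"z_{col}"] = (x - mu[col]) / sigma[col]
    return ztable, mu, sigma


def composite_scores(ztable: pd.DataFrame) -> pd.Series:
    """Unweighted mean of the four z-score columns, per stimulus."""
    missing = [c for c in Z_COLUMNS if c not in ztable.columns]
    if missing:
        raise ValidationError(f"missing z-score columns: {missing}")
    return ztable[list(Z_COLUMNS)].mean(axis=1)


def assign_blocks(
    composites: Sequence[float], labels: Sequence[str] = BLOCK_LABELS
) -> list[str]:
    """Rank-based quantile binning into ascending load blocks.

    With n divisible by the number of bins and distinct values the split is
    exactly equal-sized (4/4/4 for 12 stimuli and 3 bins); otherwise block
    sizes differ by at most one, the larger blocks sitting at the low end.
    Ties are broken by stable input order with a warning, since equal
    composites have no principled ordering.
    """
    values = np.asarray(list(composites), dtype=float)
    n = len(values)
    k = len(labels)
    if n < k:
        raise ValidationError(f"need at least {k} stimuli to form {k} blocks, got {n}")
    if np.ptp(values) == 0.0:
        raise ValidationError("all composite scores are equal: blocks undefined")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    bins = ranks * k // n
    # a tie straddles a bin edge iff two equal values land in different bins
    for v in np.unique(values):
        idx = np.nonzero(values == v)[0]
        if len(idx) > 1 and len(set(bins[idx])) > 1:
            warnings.warn(
                "tied composite scores straddle a block boundary; "
                "broken by input order",
                stacklevel=2,
            )
            break
    return [labels[b] for b in bins]


def profile_features(
    features: Sequence[FeatureVector],
    roles: Optional[dict[str, str]] = None,
    config: Optional[FeatureConfig] = None,
) -> ProfileTable:
    """Build a full profile from already-extracted feature vectors.

    This is the entry point when raw features are known but the original
    texts are not (e.g. published feature tables).
    """
    ztable, mu, sigma = zscore_features(features)
    composite = composite_scores(ztable)
    blocks = assign_blocks(composite.to_numpy())
    table = pd.DataFrame(
        {
            "id": [f.stimulus_id for f in features],
            "role": [
                (roles or {}).get(f.stimulus_id, "") for f in features
            ],
            "sentence_count": [f.sentence_count for f in features],
            "word_count": [f.word_count for f in features],
            "avg_sentence_length": [f.avg_sentence_length for f in features],
            "complex_ratio": [f.complex_ratio for f in features],
            "estimated_ius": [f.estimated_ius for f in features],
        }
    )
    for col in Z_COLUMNS:
        table[col] = ztable[col].to_numpy()
    table["composite"] = composite.to_numpy()
    table["block"] = blocks
    return ProfileTable(table=table, mu=mu, sigma=sigma, config=config)


def profile_corpus(
    corpus: StimulusCorpus, config: Optional[FeatureConfig] = None
) -> ProfileTable:
    """Extract features from corpus texts, then normalize, score and bin."""
    cfg = config or FeatureConfig()
    features = [extract_features(rec, cfg) for rec in corpus]
    roles = {rec.stimulus_id: rec.role for rec in corpus}
    return profile_features(features, roles=roles, config=cfg)
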