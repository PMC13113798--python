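"""Human-readable report rendering.

Markdown tables are display-rounded views (features to 2 decimals,
composites to 3); the CSV/JSON artifacts always carry full precision.
"""

from __future__ import annotations

from .outcomes import AnalysisSummary
from .profiling import ProfileTable


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines += ["| " + " | ".join(row) + " |" for row in rows]
    return "\n".join(lines) + "\n"


def profile_markdown(profile: ProfileTable) -> str:
    """Profile table in published column order, display-rounded."""
    header = [
        "Story", "Sentence count", "Word count", "Avg sentence length",
        "Complex sentence ratio", "Estimated IUs", "Composite score", "Load block",
    ]
    rows = []
    for r in profile.table.itertuples():
        rows.append(
            [
                str(r.id),
                str(int(r.sentence_count)),
                str(int(r.word_count)),
                f"{r.avg_sentence_length:.2f}",
                f"{r.complex_ratio:.2f}",
                str(int(r.estimated_ius)),
                f"{r.composite:.3f}",
                str(r.block),
            ]
        )
    meta = (
        f"\nNormalization: population-σ z-scores over n={len(profile.table)} stimuli."
    )
    if profile.config is not None:
        cfg = profile.config
        meta += (
            f" Keyword matching: {cfg.iu_match_mode}, "
            f"case_insensitive={cfg.case_insensitive}."
        )
    return "# Structural profile\n\n" + _md_table(header, rows) + meta + "\n"


def summary_markdown(summary: AnalysisSummary) -> str:
    parts = ["# IU gain analysis\n"]
    parts.append("## Correlations (composite vs IU gain)\n")
    parts.append(
        _md_table(
            ["Subset", "n", "r"],
            [[c["subset"], str(c["n"]), f"{c['r']:+.2f}"] for c in summary.correlations],
        )
    )
    parts.append("\n## Mean IU gain by load block\n")
    parts.append(
        _md_table(
            ["Block", "Mean gain"],
            [[b, f"{m:.2f}"] for b, m in summary.block_means.items()],
        )
    )
    parts.append("\n## Mean IU gain by condition\n")
    parts.append(
        _md_table(
            ["Condition", "Mean gain"],
            [[c, f"{m:.2f}"] for c, m in summary.condition_means.items()],
        )
    )
    return "\n".join(parts)
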