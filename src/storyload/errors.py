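"""Exception hierarchy for storyload.

Every error raised by the library derives from :class:`StoryloadError`,
so callers (and the CLI) can catch validation problems in one place.
"""


class StoryloadError(Exception):
    """Base class for all storyload errors."""


class ValidationError(StoryloadError):
    """Input data violates a documented invariant (bad role, duplicate id, ...)."""


class CorpusLoadError(StoryloadError):
    """A manifest or a referenced stimulus file could not be read."""


class SegmentationError(StoryloadError):
    """Sentence segmentation produced no usable sentences."""


class DegenerateFeatureError(StoryloadError):
    """A feature column is constant across the corpus, so z-scores are undefined."""


class UndefinedCorrelationError(StoryloadError):
    """Pearson correlation requested on a degenerate sample (n < 3 or zero variance)."""


class JoinError(StoryloadError):
    """Profile and outcome tables do not share the same stimulus ids."""


class UnachievableSpecError(StoryloadError):
    """A synthetic-stimulus specification cannot be satisfied by construction."""
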