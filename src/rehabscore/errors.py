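"""Exception hierarchy shared across the package."""


class RehabScoreError(Exception):
    """Base class for all rehabscore errors."""


class ValidationError(RehabScoreError, ValueError):
    """A motion sequence or its components violate a structural invariant."""


class ParseError(RehabScoreError, ValueError):
    """A serialized motion file could not be parsed under the declared schema."""


class DegenerateVectorError(RehabScoreError, ValueError):
    """Cosine similarity requested for a zero-length keypoint vector."""


class DegenerateBatchError(RehabScoreError, ValueError):
    """Batch normalization requested for distances with max == mean."""


class BackendUnavailableError(RehabScoreError, RuntimeError):
    """The requested pose-estimation backend is not importable/usable here."""


class ConfigError(RehabScoreError, ValueError):
    """A run configuration file or value is invalid."""
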