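"""Exception hierarchy for the gohidi pipeline.

Every stage raises a subclass of :class:`GohidiError` so the CLI can map
failures to a stage name and a nonzero exit status.
"""


class GohidiError(Exception):
    """Base class for all gohidi errors."""


class FormatError(GohidiError):
    """A file or structured text does not parse as the documented schema."""


class FrameworkValidationError(GohidiError):
    """An indicator framework violates a structural invariant."""

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []


class RevisionError(GohidiError):
    """A revision operation targets a code that does not resolve."""


class CompletenessError(GohidiError):
    """A questionnaire does not cover every unordered pair exactly once."""


class AggregationError(GohidiError):
    """Judgment matrices cannot be pooled (mismatched group/order/scale)."""


class ScaleError(GohidiError):
    """An operation does not support the judgment-matrix scale supplied."""


class AlignmentError(GohidiError):
    """Weight vectors disagree on indicator order or length."""


class CoverageError(GohidiError):
    """A data matrix is missing columns required by the framework."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []
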