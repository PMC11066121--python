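"""Exception hierarchy shared across the toolkit."""


class EmnavError(Exception):
    """Base class for all toolkit errors."""


class InvalidParams(EmnavError, ValueError):
    """A configuration or parameter value is outside its documented range."""


class CountMismatch(EmnavError, ValueError):
    """Point lists have unequal lengths or fewer than the required minimum."""


class DegenerateFiducials(EmnavError, ValueError):
    """Fiducial constellation is collinear, duplicated, or otherwise rank-deficient."""


class EmptyInput(EmnavError, ValueError):
    """An operation requiring at least one element received none."""


class WrongRole(EmnavError, ValueError):
    """A marker with an unexpected role was passed to a role-specific operation."""


class InvalidSample(EmnavError, ValueError):
    """A tracking sample flagged invalid was used where a valid one is required."""


class MalformedRow(EmnavError, ValueError):
    """A CSV row could not be parsed into the expected record."""


class InsufficientData(EmnavError, ValueError):
    """Too few groups or observations for the requested statistic."""


class OutOfRangeScore(EmnavError, ValueError):
    """A rating score falls outside the 1-5 scale."""


class EmptyErrors(EmnavError, ValueError):
    """A run record contains no per-target errors to summarize."""


class IOFailure(EmnavError, OSError):
    """A file could not be written or read back consistently."""
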