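"""Exception hierarchy.

Validation problems (malformed inputs, broken invariants) and improper
posteriors (no prior information and no data) are distinguished because the
command-line interface maps them to different exit codes.
"""


class RubrWatchError(Exception):
    """Base class for all rubrwatch errors."""


class ValidationError(RubrWatchError, ValueError):
    """An input violates a documented invariant (CLI exit code 2)."""


class ImproperPosteriorError(RubrWatchError, ValueError):
    """The posterior is improper: flat prior and no informative data
    (CLI exit code 3)."""


class OverlapWarning(UserWarning):
    """Combined rUBR draws exceed 1: cross-category overlap is being
    double-counted by the aggregated-count model."""
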