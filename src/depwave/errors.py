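"""Exception hierarchy.

``DomainError`` marks a violated physical/mathematical precondition
(nonpositive frequency, threshold out of range, ...); ``ConfigError``
marks an unreadable or invalid run configuration. The CLI maps each to
a distinct message and a nonzero exit status.
"""


class DepwaveError(Exception):
    """Base class for all depwave errors."""


class DomainError(DepwaveError, ValueError):
    """A precondition on a physical or mathematical input was violated."""


class ConfigError(DepwaveError, ValueError):
    """A run configuration could not be read or failed validation."""


class MultiCrossoverError(DomainError):
    """The dispersion changes sign more than once on the harmonic range.

    The fco/5 energy rule assumes a single cross-over (homogeneous
    sphere); multishell dispersions must be analysed line-by-line with
    :func:`depwave.force_analysis.decompose_force` instead.
    """
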