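"""Exception hierarchy.

Validation failures (bad parameters, malformed configs) raise
:class:`ValidationError`; well-formed inputs that fall outside the
mathematical domain of an operation (below-chance operating points,
quorums sitting exactly on an asymptotic boundary) raise
:class:`NumericDomainError`.  The CLI maps the former to exit code 2
and the latter to exit code 3.
"""


class QuorumPoolError(Exception):
    """Base class for all package errors."""


class ValidationError(QuorumPoolError, ValueError):
    """A parameter or configuration failed validation."""


class EcologyError(ValidationError):
    """A decision ecology violates its invariants (degenerate costs,
    non-separated cue means, prior outside (0, 1), ...)."""


class NumericDomainError(QuorumPoolError, ValueError):
    """Input is valid but outside the domain where the quantity is defined."""


class BelowChanceError(NumericDomainError):
    """Operating point lies on or below the chance diagonal
    (true positive rate <= false positive rate).

    Such a decision-maker could improve both rates simultaneously by
    inverting every decision; relabelling is the caller's job, so the
    quorum interval is undefined here.
    """


class BoundaryQuorumError(NumericDomainError):
    """Quorum coincides exactly with a_plus or 1 - a_minus, where the
    law-of-large-numbers argument for the asymptotic group accuracy
    breaks down."""
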