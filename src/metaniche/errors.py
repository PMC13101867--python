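"""Exception hierarchy for metaniche."""


class MetanicheError(Exception):
    """Base class for all package errors."""


class ValidationError(MetanicheError):
    """Invalid user input or violated data-type invariant."""


class InfeasibleError(MetanicheError):
    """An optimization problem has no feasible solution."""


class UnboundedModelError(MetanicheError):
    """The FBA objective is unbounded — the network leaks flux.

    Carries ``escape``, the reaction id of an unbounded flux when it can be
    identified, to help locate the mass-balance defect.
    """

    def __init__(self, message: str, escape: str | None = None):
        super().__init__(message)
        self.escape = escape
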