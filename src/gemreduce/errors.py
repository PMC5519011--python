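"""Exception hierarchy for model IO, configuration and lumping failures."""


class GemReduceError(Exception):
    """Base class for all package errors."""


class FormatError(GemReduceError):
    """A model or config file could not be parsed under the named dialect."""


class IntegrityError(GemReduceError):
    """A structural invariant of a model is violated (e.g. duplicate ids)."""


class ConfigError(GemReduceError):
    """A user-supplied selection/medium/cofactor entry does not resolve."""


class GPRParseError(GemReduceError):
    """A gene-protein-reaction rule string is malformed."""


class InfeasibleError(GemReduceError):
    """An LP/MILP has no feasible solution under the given constraints."""


class UnreachableBBBError(InfeasibleError):
    """A biomass building block cannot be synthesized under the medium."""

    def __init__(self, bbb_id: str, message: str = ""):
        self.bbb_id = bbb_id
        super().__init__(message or f"BBB {bbb_id!r} unreachable under medium")


class BalanceError(GemReduceError):
    """A lumped reaction leaves a non-core intermediate unbalanced."""


class OracleSizeError(GemReduceError):
    """A brute-force oracle was invoked on a problem above its size guard."""
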