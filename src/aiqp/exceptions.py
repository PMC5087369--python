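"""Exception hierarchy.

All package-specific failures derive from :class:`AIQPError` so callers can
catch everything from one base, while each class also subclasses the closest
builtin (ValueError / RuntimeError) for idiomatic handling.
"""


class AIQPError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(AIQPError, ValueError):
    """A parameter violates its stated precondition (e.g. sigma <= 0)."""


class InvalidInputError(AIQPError, ValueError):
    """Input data is malformed (dimension mismatch, empty input, ...)."""


class DegenerateSignalError(AIQPError, ValueError):
    """The target signal has no energy (y'y == 0) and cannot be analysed."""


class PartialSelectionError(AIQPError, RuntimeError):
    """Greedy center selection ran out of numerically independent candidates.

    Attributes
    ----------
    n_placed : int
        Number of centers placed before the candidate pool degenerated.
    requested : int
        Number of centers that was asked for.
    """

    def __init__(self, n_placed: int, requested: int):
        self.n_placed = n_placed
        self.requested = requested
        super().__init__(
            f"only {n_placed} of {requested} requested RBF centers could be "
            "placed before all remaining candidates became numerically "
            "dependent on the selected set"
        )


class NoQRSDetectedError(AIQPError, RuntimeError):
    """No sustained threshold crossing found in the vector magnitude."""


class EmptyEnsembleError(AIQPError, ValueError):
    """Every beat of an ensemble was rejected (or none was supplied)."""
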