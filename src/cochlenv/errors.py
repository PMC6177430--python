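"""Exception hierarchy for cochlenv."""


class CochlenvError(Exception):
    """Base class for all cochlenv errors."""


class InvalidParameterError(CochlenvError, ValueError):
    """A parameter is non-finite, out of range, or inconsistent."""


class SamplingRateError(CochlenvError, ValueError):
    """Sample rate too low for the requested stimulus/analysis."""


class RampError(CochlenvError, ValueError):
    """Ramp duration incompatible with the signal duration."""


class BinAlignmentError(CochlenvError, ValueError):
    """Requested frequency does not fall on an exact Fourier bin."""


class UnitError(CochlenvError, ValueError):
    """Signal units incompatible with the requested operation."""


class MissingPhaseError(CochlenvError, ValueError):
    """A phase sweep lacks a phase required by the statistic."""


class ContractError(CochlenvError, ValueError):
    """A generator was asked to violate its construction guarantees."""


class DegenerateDesignError(CochlenvError, ValueError):
    """Regression design matrix has no usable variation."""


class AllSweepsRejectedError(CochlenvError, RuntimeError):
    """Artifact rejection discarded every sweep."""


class EmptyInputError(CochlenvError, ValueError):
    """A statistical routine received an empty sample set."""
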