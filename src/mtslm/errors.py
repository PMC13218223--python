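"""Exception hierarchy.

Data problems (bad CSV, non-binary response, missing values) raise
:class:`DataError`; malformed model specifications raise :class:`SpecError`;
numerical failures of the likelihood machinery raise subclasses of
:class:`NumericalError`.  The CLI maps DataError/SpecError to exit code 2 and
NumericalError to exit code 3.
"""


class MTSLMError(Exception):
    """Base class for all package errors."""


class DataError(MTSLMError):
    """Invalid input data (missing values, non-binary response, ...)."""


class SpecError(MTSLMError):
    """Invalid spline specification (unsorted knots, bad degree, ...)."""


class NumericalError(MTSLMError):
    """Base class for numerical failures during fitting."""


class SingularInformationError(NumericalError):
    """Design matrix rank-deficient / Fisher information not invertible."""


class SeparationError(NumericalError):
    """(Quasi-)complete separation detected: the Bernoulli MLE diverges.

    Wald intervals are meaningless in this regime; the usual remedy is a
    sparser knot configuration.
    """


class ConvergenceError(NumericalError):
    """Newton-Raphson failed to converge within the iteration budget."""


class ExperimentError(MTSLMError):
    """A Monte-Carlo experiment is invalid (too few / too many failed runs)."""
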