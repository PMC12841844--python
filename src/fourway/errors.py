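"""Exception hierarchy.

All fourway errors derive from :class:`FourwayError`; most are also
``ValueError`` subclasses so that generic callers can catch them idiomatically.
"""


class FourwayError(Exception):
    """Base class for all errors raised by fourway."""


class ParameterError(FourwayError, ValueError):
    """An argument value violates a precondition (e.g. a negative dispersion)."""


class InputError(FourwayError, ValueError):
    """An input object is malformed or inconsistent (e.g. disjoint gene universes)."""


class DesignError(FourwayError, ValueError):
    """The sample design cannot support the requested operation."""


class ContrastError(FourwayError, ValueError):
    """A contrast references unknown or identical group labels."""


class NormalizationError(FourwayError, RuntimeError):
    """Size-factor estimation is impossible (no gene expressed in all samples)."""


class DegenerateDistributionError(FourwayError, RuntimeError):
    """A distribution lacks the structure an estimator needs (e.g. no density valley)."""
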