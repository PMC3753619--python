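"""Exception hierarchy.

``ValidationError`` covers malformed user input (sequences, configs, specs);
``AnalysisError`` covers data that is well-formed but cannot be analysed
(e.g. a trace with no melting transition). The CLI maps these to exit
codes 2 and 3 respectively.
"""


class QuadmeltError(Exception):
    """Base class for all package errors."""


class ValidationError(QuadmeltError, ValueError):
    """Malformed input: bad sequence alphabet, bad config, bad spec."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside the ACGT alphabet."""


class PairingError(ValidationError):
    """Two strands cannot be paired position-by-position."""


class AnalysisError(QuadmeltError, RuntimeError):
    """A melting trace cannot be analysed."""


class NoTransitionError(AnalysisError):
    """The folded fraction never crosses 0.5 inside the temperature range."""


class DegenerateBaselineError(AnalysisError):
    """Folded and unfolded baselines coincide at a temperature in use."""


class UndefinedEquilibriumError(AnalysisError):
    """Equilibrium constant requested at theta = 0 or theta = 1."""
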