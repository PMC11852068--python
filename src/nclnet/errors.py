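"""Exception hierarchy for the pipeline.

All exceptions derive from :class:`NclnetError` so callers can catch the
package's failures with a single clause; each subclass also derives from the
closest builtin so idiomatic ``except ValueError`` code keeps working.
"""


class NclnetError(Exception):
    """Base class for all package errors."""


class ConfigError(NclnetError, ValueError):
    """An invalid configuration value; the message names the field."""


class ParameterError(NclnetError, ValueError):
    """An invalid operation parameter (window length, band edge, decoder name...)."""


class SamplingError(NclnetError, ValueError):
    """Sampling rate incompatible with the requested filtering."""


class DataError(NclnetError, ValueError):
    """Malformed data (asymmetric weight matrix, ragged feature table...)."""
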