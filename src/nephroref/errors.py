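"""Exception hierarchy used across the package."""


class NephrorefError(Exception):
    """Base class for all package errors."""


class ConfigError(NephrorefError):
    """A configuration field is invalid; the message names the field."""


class InputError(NephrorefError):
    """A record or laboratory value violates an operation precondition."""


class DataConsistencyError(NephrorefError):
    """Linked tables disagree (e.g. an outcome date before an index date)."""


class FitError(NephrorefError):
    """A model fit failed or did not converge."""
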