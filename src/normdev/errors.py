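"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration field is missing, malformed or out of range."""


class ValidationError(ValueError):
    """Input data violate a table invariant (range, completeness, typing)."""


class FitError(RuntimeError):
    """A model could not be estimated from the data provided."""
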