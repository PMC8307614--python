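"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is outside its admissible range."""


class InputError(ValueError):
    """Input data (images, fields, files) violate a precondition."""


class UndefinedMetricError(ValueError):
    """A metric has no defined value on the given field (e.g. no valid vectors).

    Raised instead of silently returning 0 so that callers can distinguish
    "no motion information" from "zero net motion".
    """


class UndefinedEdgeError(ValueError):
    """An edge position cannot be determined (e.g. empty tissue mask)."""
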