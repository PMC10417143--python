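"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a parameter, config file, or metadata field is invalid."""


class EnumerationLimitError(ValueError):
    """Raised when an exact permutation enumeration would be too large.

    Callers should fall back to :func:`layerquant.permutation.monte_carlo_permutation`.
    """
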