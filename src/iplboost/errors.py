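"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (configuration errors → 2, data
errors → 3); library users catch them like ordinary ``ValueError``s.
"""


class IplBoostError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(IplBoostError):
    """Invalid parameters, geometry, or run configuration."""


class DataError(IplBoostError):
    """Invalid or empty input data (trajectories, samples, curves)."""
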