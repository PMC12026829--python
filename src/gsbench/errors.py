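"""Exception hierarchy used across the package."""


class GsbenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GsbenchError, ValueError):
    """Invalid configuration value (dimensions, ranges, sampler settings)."""


class DegenerateInputError(GsbenchError, ValueError):
    """Input that is technically well-formed but carries no usable signal
    (all markers monomorphic, constant phenotypes, zero MAD, ...)."""


class InputError(GsbenchError, ValueError):
    """Malformed user-supplied data (length mismatches, duplicate IDs, ...)."""
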