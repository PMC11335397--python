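"""Exception hierarchy shared across the package."""


class NichecastError(Exception):
    """Base class for all package-specific errors."""


class InputError(NichecastError, ValueError):
    """Invalid user-supplied data (shapes, signs, ranges, missing fields)."""


class ConfigError(NichecastError, ValueError):
    """Configuration file failed schema validation."""


class AllIterationsDiscardedError(NichecastError, RuntimeError):
    """Every Monte Carlo iteration was screened out as unrealistic."""
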