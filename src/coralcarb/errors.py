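"""Exception types shared across the package."""


class CoralCarbError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CoralCarbError, ValueError):
    """An input lies outside the physically meaningful domain of an operation."""


class SolverError(CoralCarbError, ArithmeticError):
    """A numerical solve failed to produce a physically valid solution."""


class DesignError(CoralCarbError, ValueError):
    """An experimental design table violates the required nesting or balance."""


class ConfigError(CoralCarbError, ValueError):
    """A configuration value is missing, malformed, or inconsistent."""
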