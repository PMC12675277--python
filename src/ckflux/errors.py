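"""Exception hierarchy shared across the package."""


class CkfluxError(Exception):
    """Base class for all ckflux errors."""


class ValidationError(CkfluxError, ValueError):
    """A domain object or parameter violates its invariants."""


class ConfigurationError(CkfluxError, ValueError):
    """A configuration is incomplete or contains unknown/invalid keys."""


class UnderdeterminedError(CkfluxError, ValueError):
    """Fewer data points than free parameters."""


class DivergenceError(CkfluxError, ArithmeticError):
    """A requested quantity is unbounded (e.g. steady state with no efflux)."""


class SchemaError(CkfluxError, ValueError):
    """An input table does not conform to the expected schema."""
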