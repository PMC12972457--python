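"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class MPClockError(Exception):
    """Base class for all package errors."""


class ConfigError(MPClockError, ValueError):
    """Invalid simulation or clock configuration."""


class InputError(MPClockError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class NumericalError(MPClockError, RuntimeError):
    """A computation produced an undefined or non-finite result."""
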