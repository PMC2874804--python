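"""Exception hierarchy shared across the package."""


class DriftNetError(Exception):
    """Base class for all package errors."""


class ValidationError(DriftNetError, ValueError):
    """Invalid input data (bad residue, malformed table, shape mismatch...)."""


class ConfigurationError(DriftNetError, ValueError):
    """Inconsistent or incomplete configuration (missing pKa entry, bad scaler...)."""


class DivergenceError(DriftNetError, ArithmeticError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class IntegrityError(DriftNetError, RuntimeError):
    """A shipped data file does not match its recorded checksum."""
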