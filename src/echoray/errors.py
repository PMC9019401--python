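"""Exception taxonomy shared across the package."""


class EchoRayError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EchoRayError, ValueError):
    """A configuration value (phantom spec, scan geometry, CLI flag) is invalid."""


class DomainError(EchoRayError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FormatError(EchoRayError, ValueError):
    """A file is not in the expected on-disk format."""


class CalibrationError(EchoRayError, ValueError):
    """A standard curve cannot be used for calibration (e.g. non-monotone)."""


class DataIntegrityError(EchoRayError, RuntimeError):
    """A bundled data file does not match its recorded checksum."""
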