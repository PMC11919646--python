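"""Exception hierarchy.

Validation problems (bad configs, bad parameters) and data-integrity problems
(inconsistent input tables) are distinguished so the CLI can map them to
distinct exit codes (2 and 3 respectively).
"""


class SedrateError(Exception):
    """Base class for all package errors."""


class ConfigError(SedrateError):
    """Invalid configuration or parameter value."""


class CalibrationError(ConfigError):
    """Invalid bead standard or calibration curve (e.g. non-monotone peaks)."""


class UnitError(ConfigError):
    """Unsupported or incompatible unit in a rate conversion."""


class DataIntegrityError(SedrateError):
    """Input tables are internally inconsistent (duplicates, impossible counts)."""
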