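"""Exception hierarchy used across the package."""


class ExotierError(Exception):
    """Base class for all package-specific errors."""


class InputError(ExotierError):
    """An input file is missing or unreadable."""


class FormatError(ExotierError):
    """An input file is readable but does not follow the expected layout."""


class ConfigError(ExotierError):
    """Invalid configuration (thresholds, model parameters, ...)."""


class DomainError(ExotierError, ValueError):
    """A value falls outside the validity domain of a calculation."""


class PedigreeError(ExotierError):
    """A pedigree table is malformed or inconsistent with the cohort."""


class FixtureSpecError(ExotierError):
    """A fixture blueprint demands contradictory evidence."""


class EnrichrUnavailable(ExotierError):
    """The EnrichR web service could not be reached."""
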