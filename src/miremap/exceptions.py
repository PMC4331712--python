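"""Exception hierarchy shared across miremap modules."""


class MiremapError(Exception):
    """Base class for all miremap errors."""


class ConfigError(MiremapError):
    """Invalid configuration value or combination."""


class ParseError(MiremapError):
    """Malformed input record; carries the offending token / line where known."""


class SizingError(ConfigError):
    """A planted structure does not fit the space allotted to it."""


class FixtureIntegrityError(MiremapError):
    """Packaged fixture content does not match its recorded checksum."""


class UnmappedNameWarning(UserWarning):
    """A miRNA name was not found in the alias table and passed through unchanged."""
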