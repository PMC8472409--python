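"""Exception hierarchy.

All package errors derive from :class:`PanelKinkError` so callers can catch
one base class; subclasses also derive from the closest builtin (ValueError,
KeyError) so generic handling keeps working.
"""


class PanelKinkError(Exception):
    """Base class for all panelkink errors."""


class SchemaError(PanelKinkError, ValueError):
    """A required column is missing or a table violates its schema."""


class ParseError(PanelKinkError, ValueError):
    """A cell could not be parsed; the message cites the offending row."""


class DataIntegrityError(PanelKinkError, ValueError):
    """Structural violation of panel invariants (e.g. duplicated period)."""


class JoinError(PanelKinkError, KeyError):
    """An individual is missing from a table that must be joinable."""


class ConfigError(PanelKinkError, ValueError):
    """An invalid simulation or estimation configuration."""


class SingularityError(PanelKinkError, ValueError):
    """A matrix required to be invertible is (numerically) singular."""


class IdentificationError(PanelKinkError, ValueError):
    """Model not identified (e.g. fewer instruments than endogenous columns)."""


class TableLookupError(PanelKinkError, KeyError):
    """A key is absent from a bundled constants table."""
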