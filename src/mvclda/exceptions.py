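"""Exception hierarchy for mvclda.

All library-raised errors derive from :class:`MvcldaError` so callers can
catch the package's failures with a single except clause while still
distinguishing identifier problems from numerical ones.
"""


class MvcldaError(Exception):
    """Base class for all errors raised by mvclda."""


class IdentifierError(MvcldaError, KeyError):
    """An lncRNA or disease identifier is unknown or duplicated."""


class OntologyError(MvcldaError, ValueError):
    """The disease ontology violates its structural contract (e.g. a cycle)."""


class ParseError(MvcldaError, ValueError):
    """A text input file is malformed; message carries file and line context."""


class ConfigError(MvcldaError, ValueError):
    """A configuration value violates its invariants."""


class NumericalError(MvcldaError, ArithmeticError):
    """A numerical computation degenerated (division by zero, non-finite values)."""
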