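"""Exception hierarchy."""


class EdafoldError(Exception):
    """Base class for package errors."""


class FragmentParseError(EdafoldError, ValueError):
    """A fragment file line could not be parsed."""


class FragmentStructureError(EdafoldError, ValueError):
    """A fragment file is structurally inconsistent (counts, windows)."""


class ConfigurationError(EdafoldError, ValueError):
    """Invalid configuration (window size mismatch, unknown term, ...)."""
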