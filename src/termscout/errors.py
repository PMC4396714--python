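"""Exception hierarchy."""


class TermscoutError(Exception):
    """Base class for all package errors."""


class CorpusError(TermscoutError):
    """Corpus loading / preparation failure (unreadable path, bad encoding...)."""


class DictionaryError(TermscoutError):
    """Terminology dictionary could not be read or is empty."""


class ConfigurationError(TermscoutError):
    """Invalid run configuration (thresholds, patterns, tagger backend)."""


class StateError(TermscoutError):
    """Operation called before its prerequisites were computed."""
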