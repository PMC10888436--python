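"""Exception hierarchy shared across the toolkit."""


class CircbactError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(CircbactError, ValueError):
    """A sequence contains a character outside the accepted alphabet."""


class TopologyError(CircbactError, ValueError):
    """An operation received a sequence with the wrong topology."""


class ModificationError(CircbactError, ValueError):
    """A modification is inconsistent with the sequence it targets."""


class ConfigurationError(CircbactError, ValueError):
    """Missing or contradictory configuration (panels, inteins, tables)."""


class DesignError(CircbactError, ValueError):
    """A construct cannot be built as requested (e.g. in-frame stop)."""
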