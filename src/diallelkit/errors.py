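"""Exception hierarchy for diallel trial data and analysis."""


class DiallelError(Exception):
    """Base class for all diallelkit errors."""


class DesignError(DiallelError):
    """Invalid mating-design parameters (too few parents, duplicate labels, ...)."""


class UnknownLabelError(DiallelError, KeyError):
    """A parent, block, regime or trait label is not part of the design/panel."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return DiallelError.__str__(self)


class IncompleteDesignError(DiallelError):
    """A balanced (entry x block x regime) layout has missing cells."""


class DuplicateObservationError(DiallelError):
    """The same (entry, block, regime) cell appears more than once."""


class PanelParseError(DiallelError):
    """A trait value could not be parsed as a finite number."""


class ConfigError(DiallelError):
    """Invalid run or generator configuration."""
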