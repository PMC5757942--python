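"""Shared exception types."""


class PleiomapError(Exception):
    """Base class for package errors."""


class FragmentedDataError(PleiomapError):
    """The epsilon-neighborhood graph is disconnected (fragmented data)."""


class DegenerateDistanceError(PleiomapError):
    """All off-diagonal distances are identical; min-max normalization is undefined."""
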