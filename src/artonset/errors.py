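"""Exception hierarchy for artonset.

All anticipated failure modes raise one of these, so callers (and the CLI)
can distinguish a detection failure from a programming error.
"""


class ArtonsetError(Exception):
    """Base class for all artonset errors."""


class FormatError(ArtonsetError):
    """A file exists but is not in a supported on-disk format."""


class UnsupportedLayoutError(FormatError):
    """A readable file uses a layout we deliberately do not support
    (e.g. EDF channels with heterogeneous sampling rates)."""


class ValidationError(ArtonsetError):
    """A container invariant was violated (non-monotonic onsets,
    non-finite samples, duplicate channel labels, ...)."""


class ParameterError(ArtonsetError):
    """Inconsistent or out-of-range user parameters."""


class NoArtefactChannelError(ArtonsetError):
    """No EEG channel produced a peak train consistent with the expected
    gradient-switch periodicity.  Carries per-channel diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoPeriodicityFoundError(ArtonsetError):
    """No channel in a segment shows cardiac-band autocorrelation strong
    enough to seed cardioballistic template construction."""


class UndefinedMetricError(ArtonsetError):
    """A performance index is undefined for the given counts
    (e.g. sensitivity with no true onsets)."""
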