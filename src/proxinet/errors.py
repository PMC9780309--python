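"""Exception hierarchy for proxinet."""


class ProxinetError(Exception):
    """Base class for all proxinet errors."""


class NamingError(ProxinetError):
    """A filename does not parse under the CID-D-DID-MA grammar."""


class RecordError(ProxinetError):
    """A signal row is malformed (non-numeric field, RSSI out of range)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class FormatError(ProxinetError):
    """A file carries an unknown dialect element (e.g. reconstruction tag)."""


class MixingError(ProxinetError):
    """Fragments from different owners/half-days were merged together."""


class UnknownBadgeError(ProxinetError):
    """An incident or mapping references a DID absent from the roster."""


class IdSpaceError(ProxinetError):
    """The requested population does not fit the DID coding scheme."""


class ScheduleError(ProxinetError):
    """A schedule template is inconsistent (overlaps, out of session)."""


class ConfigError(ProxinetError):
    """Invalid configuration value."""


class DegenerateFitError(ProxinetError):
    """A classifier cannot be fit (single-class labels, sign violation)."""


class AlignmentError(ProxinetError):
    """Two state sequences share no common slot grid."""


class BoundaryError(ProxinetError):
    """An event falls outside the segmented span."""


class CapabilityError(ProxinetError):
    """An optional component is unavailable in this installation."""


class DependencyError(ProxinetError):
    """A pipeline stage is missing its upstream outputs."""
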