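"""Exception types shared across the package."""


class NotchTrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NotchTrackError, ValueError):
    """Invalid parameter or configuration value."""


class DegenerateInputError(NotchTrackError, ValueError):
    """Input admits no meaningful result (constant image, empty sample...)."""


class PlacementError(NotchTrackError, RuntimeError):
    """Simulated cells could not be placed without illegal overlap."""


class DomainError(NotchTrackError, ValueError):
    """Query outside the domain of a function (e.g. time outside lifetime)."""


class InputError(NotchTrackError, ValueError):
    """Malformed input data (duplicates, shape mismatch...)."""


class InsufficientDataError(NotchTrackError, ValueError):
    """Not enough usable samples for the requested fit or profile."""


class EditError(NotchTrackError, ValueError):
    """A manual tracking edit violates a link-table invariant."""


class FormatError(NotchTrackError, ValueError):
    """File content does not match the expected on-disk format."""
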