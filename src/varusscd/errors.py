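"""Exception hierarchy for the varus stress-MRI measurement pipeline."""


class VarusSCDError(Exception):
    """Base class for all package errors."""


class FormatError(VarusSCDError):
    """Input file is not a readable 3D integer label volume."""


class ValidationError(VarusSCDError):
    """A label volume violates a structural requirement (e.g. missing role)."""


class SizingError(VarusSCDError):
    """Phantom geometry does not fit inside the requested volume."""


class ParameterError(VarusSCDError):
    """Phantom parameters are inconsistent (e.g. negative gap)."""


class CollisionError(VarusSCDError):
    """Rigid femur motion produced overlapping femur/tibia labels."""


class FrameError(VarusSCDError):
    """Joint coordinate frame could not be constructed."""


class MeasurementDomainError(VarusSCDError):
    """No valid measurement columns / grid points remain."""


class PairingError(VarusSCDError):
    """Two tables or maps that must share keys/grids do not."""


class DesignError(VarusSCDError):
    """Study table is not a complete crossed repeated-measures design."""
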