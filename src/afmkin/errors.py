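"""Exception types raised by the kinematics engine."""


class AfmError(Exception):
    """Base class for all model errors."""


class MissingMarkerError(AfmError, KeyError):
    """A marker required by a construction is absent from the marker set."""

    def __init__(self, name, context=""):
        self.marker = name
        msg = f"marker {name!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class InvalidGeometryError(AfmError, ValueError):
    """Degenerate geometry: zero-length axis, collinear points, parallel axes."""


class CalibrationError(AfmError, ValueError):
    """Calibration inputs are unusable (empty static trial, bad lengths...)."""
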