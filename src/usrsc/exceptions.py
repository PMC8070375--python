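"""Exception hierarchy for usrsc."""


class USRSCError(Exception):
    """Base class for all usrsc errors."""


class GeometryError(USRSCError):
    """Invalid or unusable field-of-view geometry."""


class DegenerateFOVError(GeometryError):
    """Operation requires a convex/sector FOV but got a linear (degenerate) one."""


class ApexUndefinedError(GeometryError):
    """Point coincides with the apex (radius 0, r_c = 0): angle is undefined."""


class EmptyMaskError(USRSCError):
    """Binarized UIR contains no foreground: the frame has no visible FOV."""


class BoundaryDetectionError(USRSCError):
    """Fewer than two supported boundary lines: candidate linear FOV."""


class CanvasError(USRSCError):
    """FOV is not representable on the requested canvas (zero visible area)."""
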