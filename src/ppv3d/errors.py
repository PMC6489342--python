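"""Exception types shared across the package."""


class PPVError(Exception):
    """Base class for all ppv3d errors."""


class ConfigurationError(PPVError):
    """A user-supplied option or column mapping is invalid."""


class TrajectoryError(PPVError):
    """A trajectory violates its invariants (ordering, duplicates, length)."""


class InfeasibleSegmentError(PPVError):
    """A segment's observed speed exceeds the supplied maximum speed.

    Raised when v_max * dt < d, i.e. the accessibility ellipsoid would have
    an imaginary minor axis. Usually signals a bad v_max override.
    """
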