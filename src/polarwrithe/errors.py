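"""Exception types raised by the curve-topology routines."""


class CurveError(ValueError):
    """Malformed or unusable input curve."""


class DegenerateAxisError(CurveError):
    """The curve is (nearly) flat with respect to the vertical reference axis.

    The polar writhe is defined relative to a fixed vertical direction; a curve
    whose height is constant everywhere has no turning-point structure.  Choose
    a different reference axis (e.g. pre-rotate the frame) and retry.
    """


class SelfIntersectionError(CurveError):
    """Two curve strands (or a strand and an end extension) coincide at a
    shared height, so the mutual winding angle is undefined there."""
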