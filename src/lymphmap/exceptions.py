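"""Exception hierarchy for lymphmap."""


class LymphmapError(ValueError):
    """Base class for all lymphmap errors."""


class ShapeMismatchError(LymphmapError):
    """Arrays that must be co-registered do not share shape or spacing."""


class LandmarkError(LymphmapError):
    """Landmark indices violate ordering or extent constraints."""


class EmptySliceError(LymphmapError):
    """A cross-sectional slice contains no usable (non-noise) voxels."""


class ContrastError(LymphmapError):
    """Phantom tissue means violate the channel-dominance contrast assumption."""


class GeometryError(LymphmapError):
    """Phantom geometry is inconsistent or an excess target exceeds capacity."""


class DegenerateDataError(LymphmapError):
    """Statistical input is degenerate (constant sample, zero variance, ...)."""
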