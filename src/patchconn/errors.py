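"""Exception hierarchy for patchconn."""


class PatchConnError(Exception):
    """Base class for all patchconn errors."""


class LayerReadError(PatchConnError):
    """The vector file could not be read or is not a usable layer."""


class GeographicCRSError(LayerReadError):
    """The layer is in geographic (degree) coordinates; metric units required."""


class EmptyLayerError(LayerReadError):
    """The layer contains no polygon features."""


class DuplicatePatchIdError(PatchConnError):
    """Two patches carry the same identifier."""


class InvalidBoundaryError(PatchConnError):
    """The clipping boundary is invalid and could not be repaired."""


class ConeforFormatError(PatchConnError):
    """A Conefor node/connection file is malformed or inconsistent."""


class ThresholdExceedsCutoffError(PatchConnError):
    """A dispersal threshold is larger than the edge list cutoff."""


class SinglePatchError(PatchConnError):
    """Node-removal importance is undefined for a single-patch graph."""


class PlacementError(PatchConnError):
    """Synthetic patch placement failed (extent too small for the sizes drawn)."""
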