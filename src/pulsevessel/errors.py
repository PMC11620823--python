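"""Exception hierarchy for the pipeline."""


class PulseVesselError(Exception):
    """Base class for all pipeline errors."""


class GeometryMismatchError(PulseVesselError):
    """Two images that must share a voxel grid do not."""


class EmptyRegionError(PulseVesselError):
    """A segmentation step produced or received an empty voxel set."""


class QualityControlError(PulseVesselError):
    """An input failed a quality gate in strict mode."""
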