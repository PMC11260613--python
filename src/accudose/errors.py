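"""Exception hierarchy shared across the pipeline."""


class AccudoseError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AccudoseError):
    """Grids, masks or fields do not share the required geometry."""


class InvalidParameterError(AccudoseError, ValueError):
    """A numeric parameter is outside its admissible range."""


class InvalidStructureError(AccudoseError):
    """A structure mask is missing, empty, or violates a containment rule."""


class LabelCollisionError(AccudoseError):
    """Summed structure labels are not uniquely decodable."""


class InsufficientVolumeError(AccudoseError):
    """A dose-at-volume query exceeds the structure's volume."""


class PairingError(AccudoseError):
    """Paired plan-comparison inputs cannot be matched up."""


class ConfigurationError(AccudoseError):
    """A pipeline or training configuration is inconsistent."""


class ShapeError(AccudoseError):
    """Array shape incompatible with the model or grid contract."""
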