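"""Exception hierarchy for the perturbation-repeatability pipeline."""


class PerturbradError(Exception):
    """Base class for all package errors."""


class FormatError(PerturbradError):
    """A file could not be read as a supported volume format."""


class GeometryError(PerturbradError):
    """Image/mask geometries disagree (shape, spacing, origin or slice layout)."""


class EmptyROIError(PerturbradError):
    """A region of interest contains no foreground voxels."""


class ParameterError(PerturbradError):
    """A configuration or analysis parameter is outside its valid domain."""
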