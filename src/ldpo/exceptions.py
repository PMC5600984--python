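"""Exception hierarchy shared across the pipeline stages."""


class LdpoError(Exception):
    """Base class for all package errors."""


class GeometryError(LdpoError, ValueError):
    """Shape, spacing or window geometry is inconsistent."""


class DimensionalityError(GeometryError):
    """An image is not a 3-D volume."""


class DegenerateRangeError(LdpoError, ValueError):
    """Intensity rescaling requested on a constant image."""


class DomainError(LdpoError, ValueError):
    """A parameter lies outside its admissible domain."""


class InitializationError(LdpoError, ValueError):
    """Mixture initialization is impossible on the given data."""


class DegenerateModelError(LdpoError, ValueError):
    """A tissue model parameter makes the likelihood degenerate."""


class DegenerateClassError(LdpoError, RuntimeError):
    """A tissue class lost all posterior mass during EM."""


class EmptyRegionError(LdpoError, ValueError):
    """An operation requires a non-empty voxel region."""


class ContractError(LdpoError, ValueError):
    """A documented precondition was violated."""


class PipelineError(LdpoError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
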