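"""Exception types shared across the package."""


class TexlaiError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(TexlaiError):
    """Experiment design has an empty factor or a non-positive count."""


class FormatError(TexlaiError):
    """A raster on disk does not match the expected band layout."""


class EmptyROIError(TexlaiError):
    """No vegetation pixels (or no valid texture window) available."""


class SceneTooSmallError(TexlaiError):
    """Rendered plot raster smaller than the texture analysis window."""


class DegenerateWindowError(TexlaiError):
    """A co-occurrence window contains no valid pixel pair at the offset."""


class UndefinedCorrelationError(TexlaiError):
    """Pearson correlation requested for a zero-variance input."""


class SearchFailureError(TexlaiError):
    """Every tuple in an index-family search was invalid."""


class TooFewSamplesError(TexlaiError):
    """Not enough samples to split into modeling and validation sets."""


class DegenerateInputError(TexlaiError):
    """Feature matrix unusable for model fitting (e.g. all-constant)."""


class ContractError(TexlaiError):
    """Caller violated an interface contract (mismatched model/combination)."""
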