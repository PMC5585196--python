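"""Exception hierarchy shared across the pipeline stages."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(PipelineError, ValueError):
    """Malformed or out-of-contract input (bad shapes, labels, counts)."""


class InvalidConfigError(PipelineError, ValueError):
    """Configuration value outside its documented range."""


class InvalidBandError(InvalidConfigError):
    """Band-pass edges incompatible with the sampling rate."""


class IncompatibleGeometryError(InvalidInputError):
    """Volumes whose grid shapes or affines do not match."""


class DegenerateRoiError(PipelineError):
    """An ROI with no voxels left (after masking or in a label volume)."""

    def __init__(self, roi_ids, message=None):
        self.roi_ids = list(roi_ids)
        super().__init__(message or f"ROI(s) with zero voxels: {self.roi_ids}")


class DegenerateSeriesError(PipelineError):
    """A time series with zero variance where a correlation is required."""

    def __init__(self, roi_names, message=None):
        self.roi_names = list(roi_names)
        super().__init__(message or f"zero-variance series: {self.roi_names}")


class CollinearityError(InvalidInputError):
    """Rank-deficient confound design matrix."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"linearly dependent confound columns: {self.columns}"
        )


class UnsupportedModelError(PipelineError):
    """A model without exposed primal linear weights."""


class ProvenanceError(PipelineError):
    """Outputs produced under different configuration hashes were mixed."""
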