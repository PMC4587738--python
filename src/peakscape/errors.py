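"""Exception hierarchy."""


class PeakscapeError(Exception):
    """Base class for all package errors."""


class FormatError(PeakscapeError):
    """A file does not conform to its declared format."""


class AnnotationError(PeakscapeError):
    """Gene annotation is inconsistent with the genome or with itself."""


class PipelineError(PeakscapeError):
    """A pipeline stage failed or its inputs are missing."""
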