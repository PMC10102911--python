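"""Package exception hierarchy.

``InputError`` marks invalid user-supplied data or configuration;
``PipelineError`` marks a failure inside an otherwise valid analysis run
(e.g., every covariate fit failing in one cross-validation fold).  The CLI
maps them to distinct exit codes.
"""


class CVRSError(Exception):
    """Base class for package errors."""


class InputError(CVRSError, ValueError):
    """Invalid input data, configuration, or arguments."""


class PipelineError(CVRSError, RuntimeError):
    """A pipeline stage failed on otherwise valid input."""
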