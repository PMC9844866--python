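"""Exception hierarchy shared across the pipeline stages."""


class WritersigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WritersigError):
    """A configuration value violates its documented bound."""


class InputError(WritersigError):
    """Input data violates a precondition (shape, sign, group sizes...)."""


class CohortIOError(WritersigError):
    """A cohort file is missing, malformed, or inconsistent."""


class ClusteringError(WritersigError):
    """Consensus clustering could not produce the requested partition."""


class PipelineError(WritersigError):
    """A pipeline stage failed; message names the stage and a remedy."""

    def __init__(self, stage: str, message: str, hint: str | None = None):
        self.stage = stage
        self.hint = hint
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
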