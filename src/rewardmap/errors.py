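"""Exception hierarchy shared across the pipeline."""


class RewardmapError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RewardmapError, ValueError):
    """A simulation spec violates its own invariants."""


class InvalidInputError(RewardmapError, ValueError):
    """An input object (table, vector, trace) violates an operation precondition."""


class PipelineError(RewardmapError, RuntimeError):
    """An end-to-end run failed; carries the stage name in the message."""
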