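class InvalidConfigError(ValueError):
    """A scenario, window, or pipeline configuration violates its invariants."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""
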