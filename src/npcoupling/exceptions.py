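class NPCouplingError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(NPCouplingError):
    """Invalid or infeasible configuration."""


class ValidationError(NPCouplingError):
    """Malformed input data (parse failures, schema violations, bad values)."""


class PipelineError(NPCouplingError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
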