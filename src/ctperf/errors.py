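"""Exception types shared across the package."""


class CTPerfError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CTPerfError, ValueError):
    """A configuration field is missing, malformed, or out of range."""


class InputError(CTPerfError, ValueError):
    """An input violates a function's contract (shape, count, range)."""


class GeometryError(CTPerfError, ValueError):
    """Image geometry is degenerate (empty mask, wall too thin, bad radii)."""


class DegenerateStatisticError(CTPerfError, ValueError):
    """A statistic is undefined on this input (zero variance, zero denominator)."""


class PipelineError(CTPerfError, RuntimeError):
    """A pipeline stage failed; carries the stage name and patient id."""

    def __init__(self, stage: str, message: str, patient_id: str | None = None):
        self.stage = stage
        self.patient_id = patient_id
        where = f"stage '{stage}'" + (f", patient '{patient_id}'" if patient_id else "")
        super().__init__(f"{where}: {message}")
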