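"""Exception hierarchy.

Every pipeline stage raises through :class:`PathgwasError` so that callers
(and the CLI) can report which stage failed without parsing messages.
"""


class PathgwasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathgwasError):
    """Invalid simulation or run configuration."""


class SimulationError(PathgwasError):
    """Synthetic-data generation failed (e.g. causal gene without SNPs)."""


class QCError(PathgwasError):
    """Quality control removed everything, or QC input was degenerate."""


class PhenotypeError(PathgwasError):
    """Phenotype preparation / dichotomization failure."""


class ParseError(PathgwasError):
    """A file could not be parsed; message names the file and line."""


class StageError(PathgwasError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[stage {stage}] {original}")
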