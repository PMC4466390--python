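"""Exception hierarchy shared across the package."""


class PdzbindError(Exception):
    """Base class for all package-specific errors."""


class PdbParseError(PdzbindError):
    """A coordinate file could not be parsed; message names the line."""


class TopologyError(PdzbindError):
    """Models in an ensemble do not share the same atom list."""


class PdbFormatError(PdzbindError):
    """A value cannot be represented in the fixed-column PDB format."""


class SelectionError(PdzbindError):
    """A selection required to be non-empty resolved to nothing."""


class GeometryError(PdzbindError):
    """Degenerate geometry: too few points, collinear ring, etc."""


class ConfigError(PdzbindError):
    """Invalid or inconsistent configuration."""


class FitError(PdzbindError):
    """Non-linear fit failed to converge from every start."""


class StageError(PdzbindError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
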