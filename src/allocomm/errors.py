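"""Exception hierarchy for allocomm."""


class AllocommError(Exception):
    """Base class for all allocomm errors."""


class StructureError(AllocommError):
    """Unreadable, empty, or malformed structure input."""


class NumberingError(AllocommError):
    """Residue-numbering conversion left the valid range."""


class SelectionError(AllocommError):
    """An atom selection matched nothing or referenced missing residues."""


class GeometryError(AllocommError):
    """Degenerate geometry (too few atoms, collinear sets) for superposition."""


class RankDeficiencyError(AllocommError):
    """Too few frames to estimate a covariance of the requested dimension."""


class EnsembleSpecError(AllocommError):
    """Invalid synthetic-ensemble specification (non-PD covariance, disconnected network)."""


class PipelineError(AllocommError):
    """Configuration or stage failure in the analysis pipeline."""
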