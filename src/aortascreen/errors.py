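"""Exception hierarchy for the screening pipeline."""


class AortaScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(AortaScreenError, ValueError):
    """Invalid input values (labels, shapes, parameters)."""


class DegenerateGeometryError(AortaScreenError):
    """Geometry too degenerate for the requested operation (e.g. no arch/iliac
    transition in the per-slice component profile)."""


class RenalPlaneNotFoundError(AortaScreenError):
    """No candidate bifurcation plane left after excluding the iliac split."""


class StageError(AortaScreenError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
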