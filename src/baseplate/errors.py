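"""Exception hierarchy.

Every error the library raises derives from :class:`BaseplateError`, so
callers (and the CLI, which maps them to exit code 2) can catch one type.
"""


class BaseplateError(Exception):
    """Base class for all errors raised by this package."""


class PDBParseError(BaseplateError):
    """Malformed PDB content; message names the offending line."""


class EnsembleError(BaseplateError):
    """Models of an ensemble disagree in atom count or naming."""


class PDBFormatError(BaseplateError):
    """Coordinates not representable in fixed-width PDB fields."""


class PigmentDefinitionError(BaseplateError):
    """Pigment residue missing Mg or ring-nitrogen atoms."""


class DihedralError(BaseplateError):
    """Undefined torsion (collinear atoms) or unknown angle name."""


class SelectionError(BaseplateError):
    """Atom selection empty after filtering."""


class InsufficientPigmentsError(BaseplateError):
    """Fewer than two pigment sites where at least two are required."""


class ParameterError(BaseplateError):
    """Invalid symmetry parameters or genome encoding."""


class RestraintError(BaseplateError):
    """Restraint table problem or unresolvable atom reference."""


class OptimizerError(BaseplateError):
    """Optimizer cannot proceed (e.g. all individuals non-finite)."""


class SpectraError(BaseplateError):
    """Spectral geometry or comparison error."""


class DensityError(BaseplateError):
    """Density map format, grid, or correlation error."""


class PipelineHalt(BaseplateError):
    """A pipeline phase produced zero survivors; maps to CLI exit 3."""

    def __init__(self, phase: str, reasons: list[str]):
        self.phase = phase
        self.reasons = reasons
        super().__init__(
            f"pipeline halted in {phase}: no surviving candidates\n"
            + "\n".join(f"  - {r}" for r in reasons)
        )
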