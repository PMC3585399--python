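"""Exception hierarchy for simulation-construction and estimation failures."""


class RlfsimError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedTemplateError(RlfsimError):
    """Requested ligand fragment kind is not one of the supported types."""


class UnsupportedCoordinationError(RlfsimError):
    """Ligand count outside the supported 4-8 range."""


class ConstructionClashError(RlfsimError):
    """Two interacting atoms were placed closer than the clash threshold."""


class FixtureNotFoundError(RlfsimError):
    """Requested transporter-site label has no packaged composition."""


class DivergenceError(RlfsimError):
    """Non-finite energy encountered during minimisation."""


class InstabilityError(RlfsimError):
    """Dynamics diverged; carries the offending step index."""

    def __init__(self, step: int, energy: float):
        self.step = step
        self.energy = energy
        super().__init__(
            f"energy diverged at step {step} (|E| = {energy:.3g} kcal/mol)"
        )


class ParameterisationError(RlfsimError):
    """An atom or bonded term could not be resolved against the parameter table."""


class InsufficientSamplingError(RlfsimError):
    """A free-energy window has too few samples to estimate an increment."""


class EstimatorError(RlfsimError):
    """A free-energy estimator failed to converge."""


class StrainContaminationError(RlfsimError):
    """Anchors built for a different ion than simulated; the no-strain condition
    of the reduced-ligand-fluctuation protocol would be violated."""


class ProtocolError(RlfsimError):
    """An alchemical leg was requested on a system that violates its protocol
    (e.g. an ion morph on an anchored system)."""


class CycleInconsistencyError(RlfsimError):
    """Cycle legs disagree on ions or ligand count."""


class SelectionError(RlfsimError):
    """Empty or invalid atom selection."""


class RdfNotConvergedError(RlfsimError):
    """The first RDF peak moved between trajectory halves; more sampling is
    needed before the radius can anchor a strain-free geometry."""
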