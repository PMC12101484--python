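"""Exception types raised across the package."""


class ActophaseError(Exception):
    """Base class for package errors."""


class BondOverstretchError(ActophaseError):
    """A FENE bond reached or exceeded its maximum extension R0."""


class SingularOverlapError(ActophaseError):
    """Two nonbonded beads overlapped (r ~ 0) with force capping disabled."""


class IntegrationBlowUpError(ActophaseError):
    """Coordinates or velocities became non-finite during integration."""


class InitializationFailureError(ActophaseError):
    """The biased initialization failed to reach a single-cluster state."""


class SinglePhaseError(ActophaseError):
    """An interfacial quantity was requested for a single-phase profile."""


class FormatError(ActophaseError):
    """A file did not conform to the expected dialect."""
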