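"""Exception hierarchy for the stenosis-assessment pipeline."""


class StenokitError(Exception):
    """Base class for all package-specific failures."""


class NoVesselSignal(StenokitError):
    """Raised when an image (or probability map) contains no vessel-like signal.

    Distinct from an empty result on purpose: downstream prompt selection must
    not silently proceed with an empty candidate set.
    """


class InconsistentInputs(StenokitError):
    """Raised when two inputs that must describe the same image disagree
    (e.g. a centerline pixel that falls on background of its own mask)."""


class DegenerateMask(StenokitError):
    """Raised for masks on which the requested morphometric quantity is
    undefined (empty mask, all-foreground image, zero reference diameter)."""


class BackendError(StenokitError):
    """A segmenter backend failed; the original exception is chained."""


class PhantomSpecError(StenokitError):
    """Invalid synthetic-phantom specification (bad severity, anomaly too
    close to a junction, overlapping anomaly extents, ...)."""
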