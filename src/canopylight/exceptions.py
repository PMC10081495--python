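"""Exception hierarchy used across the package."""


class CanopylightError(Exception):
    """Base class for all package errors."""


class DomainError(CanopylightError, ValueError):
    """An input lies outside the physically meaningful domain."""


class DegenerateAnchorError(CanopylightError, ValueError):
    """The two anchor shape values coincide; the affine rescale is undefined."""


class MissingDataError(CanopylightError, ValueError):
    """A required subset of records is empty."""


class UnidentifiableError(CanopylightError, ValueError):
    """The measurement design cannot identify the requested parameters."""


class FitError(CanopylightError, RuntimeError):
    """A least-squares fit failed outright (distinct from a flagged non-convergence)."""


class SceneError(CanopylightError, ValueError):
    """The scene description is inconsistent or cannot be realized."""


class TransportError(CanopylightError, RuntimeError):
    """The photon tracer detected an impossible event (e.g. an escaping ray)."""
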