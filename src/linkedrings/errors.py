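"""Exception types shared across the package."""


class LinkedRingsError(Exception):
    """Base class for package errors."""


class OverstretchedBondError(LinkedRingsError):
    """A FENE bond reached or exceeded its maximum extension r0.

    During dynamics this signals a (rejected) topology-violating step.
    """


class WallViolationError(LinkedRingsError):
    """A bead left the cylindrical channel (integration blow-up signal)."""


class IntegrationError(LinkedRingsError):
    """Non-finite coordinates or velocities during time stepping."""


class DegenerateGeometryError(LinkedRingsError):
    """Geometry unsuitable for a topological computation (e.g. intersecting
    segments in a Gauss-integral evaluation, or a degenerate projection that
    persists after the allowed retries)."""


class CatalogError(LinkedRingsError):
    """Unknown topology identifier or unbuildable catalog request."""


class ProtocolError(LinkedRingsError):
    """A preparation protocol was applied to an unsuitable conformation."""


class CensoredDataError(LinkedRingsError):
    """An estimator's preconditions on the input window are not met."""
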