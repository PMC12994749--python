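"""Exception hierarchy for blebsim."""


class BlebsimError(Exception):
    """Base class for all package errors."""


class GeometryError(BlebsimError):
    """Invalid or degenerate Lagrangian geometry (self-intersection, zero segment)."""


class MomentumViolationError(BlebsimError):
    """Net body force on the periodic fluid domain exceeds tolerance."""

    def __init__(self, net_force, scale):
        self.net_force = net_force
        self.scale = scale
        super().__init__(
            f"net force on fluid {net_force} exceeds momentum tolerance "
            f"(relative to total force magnitude {scale:.6g})"
        )


class ConstitutiveError(BlebsimError):
    """FENE-P conformation tensor violated SPD/extensibility beyond repair."""


class IllPosedBalanceError(BlebsimError):
    """Cortex drag coefficient vanished at a node with nonzero residual force."""


class ConfigError(BlebsimError):
    """Configuration validation failure; message lists all offending keys."""
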