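"""Model parameters for the coarse-grained linked-ring simulations.

All quantities are expressed in reduced Lennard-Jones units: the bead
diameter sigma is the unit of length, the WCA amplitude epsilon (set equal
to the thermal energy k_B*T) is the unit of energy, the bead mass m is the
unit of mass, and tau_LJ = sigma*sqrt(m/epsilon) is the unit of time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ModelParams",
    "ChannelSpec",
    "StretchProtocol",
    "BULK",
    "default_params",
    "DEFAULT_KAPPA",
    "ideal_wlc_kappa",
]

#: Sentinel channel diameter meaning "no walls" (bulk, free space).
BULK = math.inf


#: Default bending constant [k_B T].  Calibrated so that the *measured*
#: persistence length of a free self-avoiding chain -- the exponential fit
#: of <cos theta(s)> over contour separations 1-10 sigma -- equals
#: 5 sigma.  The ideal discrete-WLC inversion (:func:`ideal_wlc_kappa`,
#: ~5.70) overshoots the measured l_p by ~25% because excluded volume
#: slows the orientational decorrelation beyond about one l_p.
DEFAULT_KAPPA = 5.4


def ideal_wlc_kappa(lp_target: float = 5.0, bond_length: float = 0.9651) -> float:
    """Bending constant (in k_B*T) for which an *ideal* discrete worm-like
    chain with energy kappa*(1-cos theta) per joint has persistence length
    ``lp_target`` at the given bond length.

    Consecutive bond vectors satisfy
    ``<cos theta> = coth(kappa/kT) - kT/kappa`` and correlations decay as
    ``<cos theta(s)> = <cos theta>^(s/b)``, i.e. l_p = -b/ln<cos theta>;
    this inverts that relation numerically.  Note the self-avoiding chain
    simulated by the package decorrelates more slowly than the ideal
    chain, which is why the package default is :data:`DEFAULT_KAPPA`.
    """
    target = math.exp(-bond_length / lp_target)

    def mean_cos(k: float) -> float:
        # coth(k) - 1/k, stable for k > 1
        return 1.0 / math.tanh(k) - 1.0 / k

    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_cos(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ModelParams:
    """Force-field, integrator and thermostat constants (reduced units).

    The bending constant defaults to :data:`DEFAULT_KAPPA`, calibrated so
    that the measured persistence length of a free chain equals
    ``lp_target`` (= 5 sigma).
    """

    N: int = 120                  # beads per ring
    sigma: float = 1.0            # bead diameter (unit of length)
    epsilon: float = 1.0          # WCA amplitude, = k_B T
    fene_k: float = 30.0          # FENE spring constant [epsilon/sigma^2]
    fene_r0: float = 1.5          # FENE maximum extension [sigma]
    kappa: float = DEFAULT_KAPPA   # bending constant [epsilon]
    lp_target: float = 5.0        # persistence length [sigma]
    mass: float = 1.0             # bead mass (unit of mass)
    gamma: float = 1.0            # Langevin friction [1/tau_LJ]
    dt: float = 0.005             # integration step [tau_LJ]
    temperature: float = 1.0      # k_B T [epsilon]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.fene_r0 <= self.sigma:
            raise ValueError("fene_r0 must exceed sigma")
        if self.epsilon != self.temperature:
            raise ValueError("model convention requires epsilon == k_B T")
        if abs(self.lp_target / self.sigma - 5.0) > 1e-12:
            raise ValueError("model convention fixes lp_target = 5 sigma")

    @property
    def tau_lj(self) -> float:
        return self.sigma * math.sqrt(self.mass / self.epsilon)

    @property
    def wca_cutoff(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ChannelSpec:
    """Cylindrical channel of diameter D along x, periodic longitudinally.

    ``diameter = BULK`` (infinity) selects free space: no walls and no
    periodic boundary.  Beads interact with the wall through the WCA
    potential of the radial gap D/2 - rho, rho being the distance of the
    bead centre from the channel axis.
    """

    diameter: float = BULK        # D [sigma]; BULK sentinel = no walls
    period_x: float = 0.0         # longitudinal box length [sigma]; <=0 with BULK

    def __post_init__(self) -> None:
        if not self.is_bulk:
            if self.diameter <= 2.0:
                raise ValueError("channel diameter must exceed 2 sigma")
            if self.period_x <= 0:
                raise ValueError("confined channel requires a positive period_x")

    @property
    def is_bulk(self) -> bool:
        return math.isinf(self.diameter)

    @staticmethod
    def bulk() -> "ChannelSpec":
        return ChannelSpec(diameter=BULK, period_x=0.0)

    @staticmethod
    def for_rings(diameter: float, n_beads_total: int, sigma: float = 1.0) -> "ChannelSpec":
        """Channel with a periodic box comfortably longer than any span.

        The default box length is four times the diameter of a fully
        circular ring of the same total contour, 4*(L/pi), which exceeds
        the maximal achievable span L/2 per ring by a wide margin.
        """
        if math.isinf(diameter):
            return ChannelSpec.bulk()
        period = 4.0 * (n_beads_total * sigma / math.pi)
        return ChannelSpec(diameter=diameter, period_x=period)


@dataclass(frozen=True)
class StretchProtocol:
    """Constant-force pulling used to prepare elongated initial states.

    One bead per ring is pulled; the two forces have equal magnitude f and
    opposite longitudinal directions, so the net external force vanishes.
    """

    pulled_bead_per_ring: Optional[tuple[int, int]] = None  # None: outermost
    force_magnitude: float = 20.0     # f [k_B T / sigma]
    prep_diameter: float = 11.0       # D during preparation [sigma]
    prep_duration: float = 500.0      # tension equilibration time [tau_LJ]

    def __post_init__(self) -> None:
        if self.force_magnitude < 0:
            raise ValueError("force magnitude must be non-negative")
        if self.prep_duration <= 0:
            raise ValueError("prep_duration must be positive")


def default_params(N: int = 120, **overrides) -> ModelParams:
    """Convenience constructor with the study's default constants."""
    return ModelParams(N=N, **overrides)
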