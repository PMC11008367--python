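"""Coarse-grained energetics: WCA, FENE, bending and channel-wall terms.

The model is the standard bead-spring (Kremer-Grest) ring with a bending
rigidity: purely repulsive WCA excluded volume between every bead pair,
FENE springs along the backbone, kappa*(1 - cos theta) bending at every
joint, and a WCA wall potential acting on the radial gap between a bead
and the cylindrical channel surface.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import _kernels
from .dynamics import Conformation, _external_forces
from .errors import OverstretchedBondError, WallViolationError
from .params import ChannelSpec, ModelParams, StretchProtocol

__all__ = [
    "pair_repulsion_energy", "fene_bond_energy", "bending_energy",
    "wall_energy", "total_energy", "total_forces", "kinetic_temperature",
]


def pair_repulsion_energy(r: float, params: ModelParams | None = None) -> float:
    """WCA energy of two beads at centre distance ``r``.

    4*eps*[(sigma/r)^12 - (sigma/r)^6] + eps below the cutoff 2^(1/6) sigma,
    zero beyond it (continuous at the cutoff).
    """
    p = params or ModelParams()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= 2 ** (1 / 6) * p.sigma:
        return 0.0
    sr6 = (p.sigma / r) ** 6
    return 4.0 * p.epsilon * (sr6 * sr6 - sr6) + p.epsilon


def fene_bond_energy(r: float, params: ModelParams | None = None) -> float:
    """FENE backbone spring energy, -K/2 * r0^2 * ln(1 - (r/r0)^2)."""
    p = params or ModelParams()
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= p.fene_r0:
        raise OverstretchedBondError(
            f"bond length {r} >= r0 = {p.fene_r0} (topology-violating)")
    return -0.5 * p.fene_k * p.fene_r0 ** 2 * math.log(1.0 - (r / p.fene_r0) ** 2)


def bending_energy(conf: Conformation, params: ModelParams | None = None) -> float:
    """Total bending energy, sum of kappa*(1 - cos theta) over joints."""
    p = params or ModelParams()
    angles = conf.angles()
    b1 = conf.positions[angles[:, 1]] - conf.positions[angles[:, 0]]
    b2 = conf.positions[angles[:, 2]] - conf.positions[angles[:, 1]]
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("degenerate (zero-length) bond")
    c = np.clip(np.einsum("ij,ij->i", b1, b2) / (n1 * n2), -1.0, 1.0)
    return float(p.kappa * np.sum(1.0 - c))


def wall_energy(position: np.ndarray, channel: ChannelSpec,
                params: ModelParams | None = None) -> float:
    """WCA repulsion between one bead and the channel wall (0 in bulk)."""
    p = params or ModelParams()
    if channel.is_bulk:
        return 0.0
    rho = float(np.hypot(position[1], position[2]))
    gap = 0.5 * channel.diameter - rho
    if gap <= 0:
        raise WallViolationError("bead outside the channel radius")
    if gap >= 2 ** (1 / 6) * p.sigma:
        return 0.0
    sr6 = (p.sigma / gap) ** 6
    return 4.0 * p.epsilon * (sr6 * sr6 - sr6) + p.epsilon


def total_energy(conf: Conformation, params: ModelParams,
                 channel: ChannelSpec,
                 protocol: Optional[StretchProtocol] = None) -> float:
    """Total potential energy (pair + bond + bending + wall + pulling)."""
    e = _kernels.total_potential_energy(
        conf.positions, conf.bonds(), conf.angles(),
        params.epsilon, params.sigma, params.fene_k, params.fene_r0,
        params.kappa, channel.diameter, channel.period_x)
    if not np.isfinite(e):
        raise OverstretchedBondError("diverging bond or wall term")
    if protocol is not None:
        ext = _external_forces(conf, protocol)
        e -= float(np.sum(ext * conf.positions))
    return float(e)


def total_forces(conf: Conformation, params: ModelParams,
                 channel: ChannelSpec,
                 protocol: Optional[StretchProtocol] = None) -> np.ndarray:
    """Per-bead force field; equals -grad of :func:`total_energy`."""
    ext = _external_forces(conf, protocol)
    f = np.empty_like(conf.positions)
    status = _kernels.compute_forces(
        conf.positions, conf.bonds(), conf.angles(),
        params.epsilon, params.sigma, params.fene_k, params.fene_r0,
        params.kappa, channel.diameter, channel.period_x, ext, f)
    if status == 1:
        raise OverstretchedBondError("FENE bond at or beyond maximum extension")
    if status == 2:
        raise WallViolationError("bead outside the channel radius")
    if status == 3:
        raise ValueError("degenerate geometry in force evaluation")
    return f


def kinetic_temperature(conf: Conformation, params: ModelParams) -> float:
    """Instantaneous kinetic temperature <m v^2>/3 per bead."""
    v2 = np.sum(conf.velocities ** 2, axis=1)
    return float(params.mass * v2.mean() / 3.0)
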