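"""Conformations, trajectories and Langevin time stepping.

Positions are stored *unwrapped*: beads carry their true longitudinal
coordinate even when the channel is periodic along x.  Periodicity enters
only through minimum-image pair distances inside the force kernels, so the
longitudinal span and other metric observables can always be evaluated
directly on the stored coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .errors import (IntegrationError, OverstretchedBondError,
                     WallViolationError)
from .params import BULK, ChannelSpec, ModelParams, StretchProtocol

__all__ = ["Conformation", "Trajectory", "langevin_step", "simulate",
           "soft_relax", "maxwell_velocities"]

_STATUS_ERRORS = {
    1: OverstretchedBondError("FENE bond at or beyond maximum extension"),
    2: WallViolationError("bead outside the channel radius"),
    3: IntegrationError("non-finite coordinates during integration"),
}


def _raise_status(status: int) -> None:
    if status != 0:
        raise _STATUS_ERRORS[status]


@dataclass
class Conformation:
    """Bead positions/velocities of one or two rings (or an open chain).

    ``ring_of_bead`` holds the membership label (1 or 2) of every bead; a
    single-ring system uses label 1 throughout.  ``closed`` distinguishes
    rings (cyclic bond topology) from open chains, the latter being used
    for stiffness calibration runs.
    """

    positions: np.ndarray
    ring_of_bead: np.ndarray
    velocities: Optional[np.ndarray] = None
    closed: bool = True

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.ring_of_bead = np.asarray(self.ring_of_bead, dtype=np.int64)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.ring_of_bead.shape[0] != self.positions.shape[0]:
            raise ValueError("ring_of_bead length mismatch")

    # -- structure -----------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_rings(self) -> int:
        return int(np.unique(self.ring_of_bead).size)

    @property
    def unwrapped_x(self) -> np.ndarray:
        return self.positions[:, 0]

    def ring_indices(self, label: int) -> np.ndarray:
        return np.nonzero(self.ring_of_bead == label)[0]

    def ring_positions(self, label: int) -> np.ndarray:
        return self.positions[self.ring_of_bead == label]

    def rings(self) -> list[np.ndarray]:
        return [self.ring_positions(l) for l in sorted(np.unique(self.ring_of_bead))]

    def bonds(self) -> np.ndarray:
        """Bond index pairs: cyclic per ring, or linear for an open chain."""
        out = []
        for label in np.unique(self.ring_of_bead):
            idx = self.ring_indices(int(label))
            n = idx.size
            stop = n if self.closed else n - 1
            for i in range(stop):
                out.append((idx[i], idx[(i + 1) % n]))
        if not out:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(out, dtype=np.int64)

    def angles(self) -> np.ndarray:
        """Consecutive bead triplets carrying the bending potential."""
        out = []
        for label in np.unique(self.ring_of_bead):
            idx = self.ring_indices(int(label))
            n = idx.size
            if self.closed:
                for i in range(n):
                    out.append((idx[i], idx[(i + 1) % n], idx[(i + 2) % n]))
            else:
                for i in range(n - 2):
                    out.append((idx[i], idx[i + 1], idx[i + 2]))
        if not out:
            return np.empty((0, 3), dtype=np.int64)
        return np.asarray(out, dtype=np.int64)

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.ring_of_bead.copy(),
                            self.velocities.copy(), self.closed)

    # -- helpers -------------------------------------------------------

    def wrapped_positions(self, channel: ChannelSpec) -> np.ndarray:
        """Positions wrapped into [-period/2, period/2) along x (bulk: copy)."""
        pos = self.positions.copy()
        if not channel.is_bulk and channel.period_x > 0:
            p = channel.period_x
            pos[:, 0] -= p * np.round(pos[:, 0] / p)
        return pos

    def recenter(self) -> "Conformation":
        """Translate the centre of mass to the origin (in place)."""
        self.positions -= self.positions.mean(axis=0)
        return self

    def validate(self, params: ModelParams) -> None:
        """Raise if bond lengths violate the FENE range or beads coincide."""
        bonds = self.bonds()
        d = np.linalg.norm(self.positions[bonds[:, 0]] - self.positions[bonds[:, 1]],
                           axis=1)
        if np.any(d >= params.fene_r0):
            raise OverstretchedBondError(
                f"max bond length {d.max():.3f} >= r0 = {params.fene_r0}")
        if np.any(d <= 0):
            raise ValueError("coincident consecutive beads")


@dataclass
class Trajectory:
    """Sampled frames of one simulation run (unwrapped coordinates)."""

    times: np.ndarray                  # (n_frames,) in tau_LJ
    frames: np.ndarray                 # (n_frames, n_beads, 3)
    ring_of_bead: np.ndarray
    closed: bool = True
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.frames[i].copy(), self.ring_of_bead.copy(),
                            closed=self.closed)

    def ring_frames(self, label: int) -> np.ndarray:
        return self.frames[:, self.ring_of_bead == label, :]


def maxwell_velocities(n: int, params: ModelParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the target temperature."""
    v = rng.standard_normal((n, 3)) * np.sqrt(params.temperature / params.mass)
    v -= v.mean(axis=0)
    return v


def _external_forces(conf: Conformation,
                     protocol: Optional[StretchProtocol],
                     force_scale: float = 1.0) -> np.ndarray:
    """Constant pulling forces: one bead per ring, equal magnitude f,
    opposite longitudinal directions (net external force zero).

    The ring with the smaller mean x is pulled towards -x.  With
    ``pulled_bead_per_ring=None`` the outermost bead of each ring (the
    longitudinal extreme on its pulling side) is selected.
    """
    ext = np.zeros_like(conf.positions)
    if protocol is None or protocol.force_magnitude == 0.0:
        return ext
    labels = sorted(int(l) for l in np.unique(conf.ring_of_bead))
    if len(labels) != 2:
        raise ValueError("pulling protocol requires exactly two rings")
    f = protocol.force_magnitude * force_scale
    mean_x = {l: conf.ring_positions(l)[:, 0].mean() for l in labels}
    ordered = sorted(labels, key=lambda l: mean_x[l])  # left ring first
    for k, (ring_label, direction) in enumerate(zip(ordered, (-1.0, +1.0))):
        idx = conf.ring_indices(ring_label)
        if protocol.pulled_bead_per_ring is None:
            x = conf.positions[idx, 0]
            bead = int(np.argmin(x) if direction < 0 else np.argmax(x))
        else:
            bead = protocol.pulled_bead_per_ring[k] % idx.size
        ext[idx[bead], 0] = direction * f
    return ext


def soft_relax(conf: Conformation, params: ModelParams,
               channel: ChannelSpec, seed: int, duration: float = 5.0,
               max_disp: float = 0.01) -> Conformation:
    """Displacement-capped, overdamped push-off for freshly built states.

    Idealized embeddings can carry compressed bonds or mild steric
    overlaps whose initial forces would destabilize the integrator; a
    small time step, a hard per-step displacement cap and strong friction
    let the stored energy drain away quasi-statically.
    """
    relax = params.with_(dt=min(params.dt, 0.001),
                         gamma=max(params.gamma, 20.0))
    simulate(conf, relax, channel, duration=duration,
             sample_interval=duration, seed=seed, max_disp=max_disp)
    conf.velocities[:] = 0.0
    return conf


def langevin_step(conf: Conformation, params: ModelParams,
                  channel: ChannelSpec, rng_seed: int,
                  n_steps: int = 1,
                  protocol: Optional[StretchProtocol] = None) -> Conformation:
    """Advance ``n_steps`` velocity-Verlet/Langevin steps (in place).

    The Langevin noise stream is seeded with ``rng_seed``; with
    ``params.gamma == 0`` no noise is drawn and the step is plain NVE
    velocity Verlet.
    """
    ext = _external_forces(conf, protocol)
    if params.gamma > 0:
        _kernels.seed_rng(rng_seed % 2**32)
    samples = np.empty((0, conf.n_beads, 3))
    status, _ = _kernels.run_langevin(
        conf.positions, conf.velocities, conf.bonds(), conf.angles(),
        params.epsilon, params.sigma, params.fene_k, params.fene_r0,
        params.kappa, channel.diameter, channel.period_x, ext,
        params.mass, params.gamma, params.temperature, params.dt,
        n_steps, 0, samples)
    _raise_status(status)
    return conf


def simulate(conf: Conformation, params: ModelParams, channel: ChannelSpec,
             duration: float, sample_interval: float, seed: int,
             protocol: Optional[StretchProtocol] = None,
             equilibration: float = 0.0,
             max_disp: float = 0.0) -> Trajectory:
    """Run Langevin dynamics and return sampled frames.

    ``duration`` and ``sample_interval`` are in tau_LJ.  An optional
    ``equilibration`` stretch is run first and not sampled.  The
    conformation is advanced in place; the returned trajectory holds
    copies of the sampled (unwrapped) frames.
    """
    n_steps = int(round(duration / params.dt))
    sample_every = max(1, int(round(sample_interval / params.dt)))
    n_samples = n_steps // sample_every
    ext = _external_forces(conf, protocol)
    bonds = conf.bonds()
    angles = conf.angles()
    if params.gamma > 0:
        _kernels.seed_rng(seed % 2**32)

    if equilibration > 0:
        eq_steps = int(round(equilibration / params.dt))
        empty = np.empty((0, conf.n_beads, 3))
        status, _ = _kernels.run_langevin(
            conf.positions, conf.velocities, bonds, angles,
            params.epsilon, params.sigma, params.fene_k, params.fene_r0,
            params.kappa, channel.diameter, channel.period_x, ext,
            params.mass, params.gamma, params.temperature, params.dt,
            eq_steps, 0, empty, max_disp)
        _raise_status(status)

    samples = np.empty((n_samples, conf.n_beads, 3))
    status, written = _kernels.run_langevin(
        conf.positions, conf.velocities, bonds, angles,
        params.epsilon, params.sigma, params.fene_k, params.fene_r0,
        params.kappa, channel.diameter, channel.period_x, ext,
        params.mass, params.gamma, params.temperature, params.dt,
        n_steps, sample_every, samples, max_disp)
    _raise_status(status)
    times = (np.arange(1, written + 1) * sample_every) * params.dt
    return Trajectory(times=times, frames=samples[:written],
                      ring_of_bead=conf.ring_of_bead.copy(),
                      closed=conf.closed, seed=seed)
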