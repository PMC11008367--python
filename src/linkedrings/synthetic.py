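"""Synthetic inputs with known ground truth for testing the analyses.

These generators let every analysis stage be exercised without running
the simulator: exact parametric link embeddings, rigid-motion
trajectories, mean-reverting (Ornstein-Uhlenbeck) observable series with
a known autocorrelation time, exponentially decaying ensemble relaxation
curves, and i.i.d. exponential disengagement times for the survival fit.
All fixtures are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .catalog import catalog_conformation
from .dynamics import Conformation, Trajectory
from .errors import CatalogError
from .observables import ObservableSeries

__all__ = [
    "make_parametric_link", "make_rigid_rotation", "make_ou_series",
    "make_exp_decay_series", "make_exp_disengagement",
]


def make_parametric_link(link_id: str, n_beads: int,
                         scale: float = 1.0) -> Conformation:
    """Exact closed polygonal realization of a catalog topology.

    Ground-truth input for the topological analyses; ``scale`` rescales
    the whole conformation (topological observables must not change).
    """
    conf = catalog_conformation(link_id, n_beads)
    conf.positions *= scale
    return conf


def make_rigid_rotation(conf: Conformation, omega: float, dt: float,
                        n_frames: int,
                        axis: Optional[np.ndarray] = None) -> Trajectory:
    """Trajectory of a conformation rigidly rotating at angular velocity
    ``omega`` about ``axis`` (z by default) through its centre of mass."""
    a = np.array([0.0, 0.0, 1.0]) if axis is None else \
        np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    com = conf.positions.mean(axis=0)
    rel = conf.positions - com
    frames = np.empty((n_frames, conf.n_beads, 3))
    for k in range(n_frames):
        th = omega * dt * k
        c, s = math.cos(th), math.sin(th)
        # Rodrigues rotation
        frames[k] = (c * rel + s * np.cross(a, rel)
                     + (1 - c) * np.outer(rel @ a, a)) + com
    times = np.arange(n_frames) * dt
    return Trajectory(times=times, frames=frames,
                      ring_of_bead=conf.ring_of_bead.copy(),
                      closed=conf.closed)


def make_ou_series(tau: float, dt: float, n: int, seed: int,
                   n_replicas: int = 1, x0: float = 1.0,
                   noise: float = 1.0) -> np.ndarray:
    """Mean-reverting Gaussian (Ornstein-Uhlenbeck) series.

    Exact discretization x_{k+1} = a x_k + sqrt(1 - a^2) * noise * xi with
    a = exp(-dt/tau): the autocorrelation time is exactly ``tau``.  All
    replicas start at ``x0``, so the ensemble mean decays as
    x0 * exp(-t/tau) -- suitable for relaxation-time recovery tests.
    Returns an (n_replicas, n) array.
    """
    if tau < 0 or dt <= 0:
        raise ValueError("need tau >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    a = math.exp(-dt / tau) if tau > 0 else 0.0
    out = np.empty((n_replicas, n))
    x = np.full(n_replicas, float(x0))
    amp = noise * math.sqrt(max(0.0, 1.0 - a * a))
    for k in range(n):
        out[:, k] = x
        x = a * x + amp * rng.standard_normal(n_replicas)
    return out


def make_exp_decay_series(tau: float, dt: float, n: int,
                          equilibrium: float = 0.0,
                          initial: float = 1.0,
                          label: str = "A") -> ObservableSeries:
    """Noise-free ensemble series <A>_t = eq + (init - eq) exp(-t/tau)."""
    t = np.arange(n) * dt
    mean = equilibrium + (initial - equilibrium) * np.exp(-t / tau)
    return ObservableSeries(times=t, ensemble_mean=mean,
                            equilibrium_mean=equilibrium,
                            initial_mean=initial, label=label)


def make_exp_disengagement(lambda_rate: float, n: int, seed: int) -> np.ndarray:
    """I.i.d. exponential disengagement times with rate ``lambda_rate``.

    Feeding these to the survival analysis must recover a lifetime of
    1/lambda.
    """
    if lambda_rate <= 0:
        raise ValueError("rate must be positive")
    if n <= 0:
        raise ValueError("need at least one event time")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / lambda_rate, size=n)
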