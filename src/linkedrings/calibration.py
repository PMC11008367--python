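"""Stiffness calibration: measuring the persistence length of the model.

The operational persistence length is defined as the decay length of the
bond-orientation correlation <cos theta(s)> of a free chain, fitted over
contour separations of 1-10 sigma.  The package's default bending
constant is chosen so this measurement returns 5 sigma; note that the
self-avoiding chain decorrelates more slowly than the ideal discrete
worm-like chain, so the operational value sits below the ideal-chain
prediction for the same constant (see :func:`linkedrings.params.ideal_wlc_kappa`).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from .dynamics import Conformation, maxwell_velocities, simulate
from .params import ChannelSpec, ModelParams

__all__ = ["wlc_chain_start", "bond_correlation", "measure_persistence_length"]


def wlc_chain_start(n_beads: int, kappa: float, rng: np.random.Generator,
                    bond: float = 0.97, min_gap: float = 0.8) -> np.ndarray:
    """Ideal discrete worm-like-chain sample (rejection for overlaps).

    Drawing the start from the ideal-chain distribution removes most of
    the equilibration burden compared to a straight rod, whose slow
    global modes would otherwise bias the orientational correlations.
    """
    while True:
        pos = [np.zeros(3)]
        t = np.array([1.0, 0.0, 0.0])
        for _ in range(n_beads - 1):
            u = rng.random()
            c = 1 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
            phi = rng.random() * 2 * np.pi
            a = np.array([0, 0, 1.0]) if abs(t[2]) < 0.9 else \
                np.array([0, 1.0, 0])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            s = np.sqrt(max(0.0, 1 - c * c))
            t = c * t + s * (np.cos(phi) * e1 + np.sin(phi) * e2)
            t /= np.linalg.norm(t)
            pos.append(pos[-1] + bond * t)
        pos = np.array(pos)
        if pdist(pos).min() > min_gap:
            return pos


def bond_correlation(conf: Conformation, max_sep: int = 10) -> np.ndarray:
    """<cos theta(s)> for bead separations s = 1..max_sep of an open chain."""
    b = np.diff(conf.positions, axis=0)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return np.array([float(np.einsum("ij,ij->i", b[:-s], b[s:]).mean())
                     for s in range(1, max_sep + 1)])


def measure_persistence_length(seeds: Sequence[int], n_beads: int = 120,
                               params: Optional[ModelParams] = None,
                               equilibration: float = 2500.0,
                               sampling: float = 500.0,
                               chunk: float = 12.5) -> float:
    """Persistence length from free-chain Langevin simulations.

    One independent chain per seed, equilibrated for ``equilibration``
    tau_LJ and sampled for ``sampling`` tau_LJ (the bond correlations are
    accumulated every ``chunk``).  The seed-pooled <cos theta(s)> is
    fitted by a * exp(-s/l_p) over contour separations 1-10 sigma by
    generalized least squares: each separation is weighted by the inverse
    across-seed standard error, which suppresses the long-separation
    points whose slow-mode fluctuations dominate the estimator variance.
    """
    p = params or ModelParams(N=n_beads)
    bulk = ChannelSpec.bulk()
    corrs = []
    for seed in seeds:
        rng = np.random.default_rng(seed + 77)
        pos = wlc_chain_start(n_beads, p.kappa, rng)
        conf = Conformation(pos, np.ones(n_beads, dtype=np.int64),
                            closed=False)
        conf.velocities = maxwell_velocities(n_beads, p, rng)
        simulate(conf, p, bulk, equilibration, equilibration, seed=seed)
        acc = []
        for k in range(int(round(sampling / chunk))):
            simulate(conf, p, bulk, chunk, chunk, seed=seed + 1000 + k)
            acc.append(bond_correlation(conf))
        corrs.append(np.mean(acc, axis=0))
    corrs = np.asarray(corrs)
    cc = corrs.mean(axis=0)
    ss = np.arange(1, 11) * 0.97
    if corrs.shape[0] > 2:
        sem = corrs.std(axis=0, ddof=1) / np.sqrt(corrs.shape[0])
        sem = np.maximum(sem, 1e-4)
    else:
        sem = np.ones_like(cc)
    popt, _ = curve_fit(lambda s, a, lp: a * np.exp(-s / lp), ss, cc,
                        p0=(1.0, 5.0), sigma=sem, absolute_sigma=True)
    return float(popt[1])
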