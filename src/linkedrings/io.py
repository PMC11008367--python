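"""Trajectory and configuration file I/O.

Two text dialects are supported for conformations/trajectories:

* XYZ, with the element tag carrying the ring label (``R1``/``R2``);
* LAMMPS dump (``id mol x y z ix``) where ``ix`` is the longitudinal
  periodic-image flag, so wrapped coordinates can be unwrapped losslessly.

Reading XYZ goes through MDAnalysis when it is available (it is part of
the supported stack); a minimal internal parser is used as fallback so the
package remains importable without it.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .dynamics import Conformation, Trajectory
from .params import BULK, ChannelSpec, ModelParams

__all__ = ["write_xyz", "read_xyz", "write_lammps_dump", "read_lammps_dump",
           "write_config", "read_config"]


def write_xyz(path, conf: Conformation, comment: str = "") -> None:
    """Write one conformation as XYZ; element tag = ring label."""
    with open(path, "w") as fh:
        _write_xyz_frame(fh, conf.positions, conf.ring_of_bead, comment)


def _write_xyz_frame(fh, positions, ring_of_bead, comment):
    fh.write(f"{positions.shape[0]}\n{comment}\n")
    for (x, y, z), r in zip(positions, ring_of_bead):
        fh.write(f"R{int(r)} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> Conformation:
    """Read a conformation written by :func:`write_xyz`."""
    try:
        import MDAnalysis as mda
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="XYZ")
            names = [n.lstrip("R") for n in u.atoms.names]
            pos = u.atoms.positions.astype(np.float64)
    except Exception:
        names, pos = _read_xyz_plain(path)
    rings = np.array([int(n) for n in names], dtype=np.int64)
    return Conformation(np.asarray(pos, dtype=np.float64), rings)


def _read_xyz_plain(path):
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    names, pos = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        names.append(parts[0].lstrip("R"))
        pos.append([float(v) for v in parts[1:4]])
    return names, np.array(pos)


def write_lammps_dump(path, traj: Trajectory, channel: ChannelSpec,
                      params: Optional[ModelParams] = None) -> None:
    """Write a trajectory in the LAMMPS dump text dialect.

    Columns: id mol x y z ix -- positions are wrapped along x inside the
    periodic box and ``ix`` holds the image flag, so that
    unwrapped_x = x + ix * period.  In bulk the box is a bounding box and
    all image flags are zero.
    """
    period = 0.0 if channel.is_bulk else channel.period_x
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            pos = traj.frames[fi]
            if period > 0:
                ix = np.floor(pos[:, 0] / period + 0.5).astype(int)
                xw = pos[:, 0] - ix * period
                xlo, xhi = -period / 2, period / 2
            else:
                ix = np.zeros(pos.shape[0], dtype=int)
                xw = pos[:, 0]
                xlo, xhi = float(xw.min() - 1), float(xw.max() + 1)
            rmax = 0.5 * channel.diameter if not channel.is_bulk else \
                float(np.abs(pos[:, 1:]).max() + 1)
            fh.write("ITEM: TIMESTEP\n%d\n" % round(
                traj.times[fi] / (params.dt if params else 0.005)))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % pos.shape[0])
            fh.write("ITEM: BOX BOUNDS pp ff ff\n")
            fh.write(f"{xlo:.10f} {xhi:.10f}\n")
            fh.write(f"{-rmax:.10f} {rmax:.10f}\n")
            fh.write(f"{-rmax:.10f} {rmax:.10f}\n")
            fh.write("ITEM: ATOMS id mol x y z ix\n")
            for i in range(pos.shape[0]):
                fh.write(f"{i + 1} {int(traj.ring_of_bead[i])} "
                         f"{xw[i]:.10f} {pos[i, 1]:.10f} {pos[i, 2]:.10f} "
                         f"{ix[i]}\n")


def read_lammps_dump(path, dt: float = 0.005,
                     sample_interval_steps: Optional[int] = None) -> Trajectory:
    """Read a dump file written by :func:`write_lammps_dump` (unwraps x)."""
    frames, times, rings = [], [], None
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        assert lines[i].startswith("ITEM: TIMESTEP")
        step = int(lines[i + 1])
        n = int(lines[i + 3])
        xlo, xhi = (float(v) for v in lines[i + 5].split())
        period = xhi - xlo
        header = lines[i + 8].split()[2:]
        cols = {c: k for k, c in enumerate(header)}
        body = lines[i + 9:i + 9 + n]
        pos = np.empty((n, 3))
        ring = np.empty(n, dtype=np.int64)
        periodic = "ix" in cols
        for line in body:
            parts = line.split()
            idx = int(parts[cols["id"]]) - 1
            ring[idx] = int(parts[cols["mol"]])
            x = float(parts[cols["x"]])
            if periodic:
                x += int(parts[cols["ix"]]) * period
            pos[idx] = (x, float(parts[cols["y"]]), float(parts[cols["z"]]))
        frames.append(pos)
        times.append(step * dt)
        rings = ring
        i += 9 + n
    return Trajectory(times=np.array(times), frames=np.array(frames),
                      ring_of_bead=rings)


def write_config(path, params: ModelParams, channel: ChannelSpec,
                 extra: Optional[dict] = None) -> None:
    """Key-value config file with all model constants in reduced units."""
    kv = {
        "N": params.N, "sigma": params.sigma, "epsilon": params.epsilon,
        "fene_k": params.fene_k, "fene_r0": params.fene_r0,
        "kappa": params.kappa, "lp_target": params.lp_target,
        "mass": params.mass, "gamma": params.gamma, "dt": params.dt,
        "temperature": params.temperature,
        "channel_diameter": "inf" if channel.is_bulk else channel.diameter,
        "period_x": channel.period_x,
    }
    if extra:
        kv.update(extra)
    with open(path, "w") as fh:
        for k, v in kv.items():
            fh.write(f"{k} = {v}\n")


def read_config(path) -> tuple[ModelParams, ChannelSpec, dict]:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    params = ModelParams(
        N=int(kv.pop("N")), sigma=float(kv.pop("sigma")),
        epsilon=float(kv.pop("epsilon")), fene_k=float(kv.pop("fene_k")),
        fene_r0=float(kv.pop("fene_r0")), kappa=float(kv.pop("kappa")),
        lp_target=float(kv.pop("lp_target")), mass=float(kv.pop("mass")),
        gamma=float(kv.pop("gamma")), dt=float(kv.pop("dt")),
        temperature=float(kv.pop("temperature")))
    d = kv.pop("channel_diameter")
    diameter = math.inf if d in ("inf", "Infinity") else float(d)
    period = float(kv.pop("period_x"))
    channel = ChannelSpec.bulk() if math.isinf(diameter) else \
        ChannelSpec(diameter=diameter, period_x=period)
    return params, channel, kv
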