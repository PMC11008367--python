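"""Experiment orchestration: equilibrium statics, out-of-equilibrium
relaxation, and geometric-entanglement (eyelet/deadlock) studies.

A single :class:`ExperimentPlan` drives all three experiment families at
a configurable scale.  The production conditions of the study are rings
of N = 120 beads, channel diameters {12, 16, 20, 24, 30, inf} sigma,
200 independent trajectories of 2e4 tau_LJ sampled every 1e2 tau_LJ with
the equilibrium window [1e4, 2e4] tau_LJ; ``scale_factor`` shrinks all of
these uniformly so that smoke-scale and production runs share one code
path.  All runs are deterministic for a fixed plan and master seed.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import topology
from .catalog import (add_eyelet, catalog_conformation, prepare_stretched,
                      _orient_along_x)
from .dynamics import Conformation, Trajectory, maxwell_velocities, simulate
from .errors import CensoredDataError, ProtocolError
from .observables import (ObservableSeries, equilibrium_average,
                          longitudinal_span, radius_of_gyration,
                          relaxation_time, survival_analysis)
from .params import BULK, ChannelSpec, ModelParams, StretchProtocol

__all__ = ["ExperimentPlan", "run_equilibrium_study", "run_relaxation_study",
           "run_entanglement_study"]

logger = logging.getLogger(__name__)

PRODUCTION_DIAMETERS = (12.0, 16.0, 20.0, 24.0, 30.0, BULK)


@dataclass(frozen=True)
class ExperimentPlan:
    """Conditions for one batch of experiments.

    ``scale_factor`` divides N, durations, window bounds and the number
    of trajectories relative to the production values, so a plan with
    scale_factor = 3 runs N = 40 rings.  Channel diameters are given in
    sigma (math.inf = bulk) and are *not* rescaled automatically: pick
    values commensurate with the scaled ring size.
    """
    link_ids: tuple[str, ...] = ("2_1^2",)
    channel_diameters: tuple[float, ...] = PRODUCTION_DIAMETERS
    n_trajectories: int = 200
    duration: float = 2e4                  # tau_LJ
    sample_interval: float = 1e2           # tau_LJ
    equilibrium_window: tuple[float, float] = (1e4, 2e4)
    n_beads: int = 120
    seed: int = 2024
    scale_factor: float = 1.0
    stretch_force: float = 20.0            # k_BT/sigma
    prep_diameter: float = 11.0            # sigma
    prep_duration: float = 500.0           # tau_LJ
    #: tension time for decorated (eyelet) and deadlocked starts: these
    #: geometric entanglements escape under sustained tension, so they
    #: receive only a short taut-ening pulse (their templates are built
    #: taut already)
    eyelet_prep_duration: float = 30.0
    deadlock_prep_duration: float = 15.0
    #: deadlock lifetime estimator: "exp_fit" (production convention) or
    #: "integral" (much lower variance at small trajectory counts)
    survival_definition: str = "exp_fit"
    ell_lk_stride: int = 1                 # physical-link analysis every k-th frame

    def scaled(self) -> "ExperimentPlan":
        """Apply ``scale_factor`` to sizes, durations and statistics."""
        s = self.scale_factor
        if s == 1.0:
            return self
        return replace(
            self,
            n_trajectories=max(2, int(round(self.n_trajectories / s))),
            duration=self.duration / s ** 2,
            sample_interval=self.sample_interval / s ** 2,
            equilibrium_window=(self.equilibrium_window[0] / s ** 2,
                                self.equilibrium_window[1] / s ** 2),
            n_beads=max(8, int(round(self.n_beads / s))),
            prep_duration=self.prep_duration / s,
            scale_factor=1.0,
        )

    def trajectory_seeds(self, stream: int) -> list[int]:
        ss = np.random.SeedSequence([self.seed, stream])
        return [int(s) % (2 ** 31 - 1)
                for s in ss.generate_state(self.n_trajectories)]


def _stable_stream(*parts) -> int:
    """Deterministic seed stream id (Python's hash() is randomized)."""
    return zlib.crc32(repr(parts).encode()) % 1000


def _channel_for(plan: ExperimentPlan, diameter: float,
                 params: ModelParams) -> ChannelSpec:
    return ChannelSpec.for_rings(diameter, 2 * plan.n_beads, params.sigma)


def _params_for(plan: ExperimentPlan, base: Optional[ModelParams]) -> ModelParams:
    p = base or ModelParams(N=plan.n_beads)
    if p.N != plan.n_beads:
        p = p.with_(N=plan.n_beads)
    return p


def _bulk_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _span_of(traj_frame: Conformation, bulk: bool,
             axis: Optional[np.ndarray]) -> float:
    return longitudinal_span(traj_frame, axis=axis if bulk else None)


# ---------------------------------------------------------------------------
# Equilibrium statics
# ---------------------------------------------------------------------------

def run_equilibrium_study(plan: ExperimentPlan,
                          params: Optional[ModelParams] = None,
                          check_topology: bool = True) -> pd.DataFrame:
    """Equilibrium <R_g>, <s>, <ell_LK> per (link, D), with SEMs and
    bulk-rescaled columns.

    Each trajectory starts from the catalog embedding, is equilibrated up
    to the start of the equilibrium window, and the last five samples per
    trajectory enter the averages (production convention).  An
    equilibration diagnostic compares the span mean over the two halves
    of the window and flags (never drops) suspicious rows.
    """
    plan = plan.scaled()
    p = _params_for(plan, params)
    rows = []
    for link in plan.link_ids:
        for D in plan.channel_diameters:
            rows.append(_equilibrium_condition(plan, p, link, D,
                                               check_topology))
    df = pd.DataFrame(rows)
    # rescaled-by-bulk columns for the collapse plots
    for col in ("rg", "span", "ell_lk"):
        df[f"{col}_over_bulk"] = np.nan
        for link in plan.link_ids:
            sel = df["link"] == link
            bulk_rows = df[sel & np.isinf(df["diameter"])]
            if len(bulk_rows) == 1 and np.isfinite(bulk_rows[col].iloc[0]):
                df.loc[sel, f"{col}_over_bulk"] = \
                    df.loc[sel, col] / bulk_rows[col].iloc[0]
    return df


def _equilibrium_condition(plan, p, link, D, check_topology) -> dict:
    bulk = math.isinf(D)
    channel = _channel_for(plan, D, p)
    t_eq0, t_eq1 = plan.equilibrium_window
    trajs = []
    axes = []
    seeds = plan.trajectory_seeds(_stable_stream(link, D))
    audit_ok = True
    for k, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        conf = catalog_conformation(link, plan.n_beads)
        _orient_along_x(conf)
        conf.velocities = maxwell_velocities(conf.n_beads, p, rng)
        if not bulk:
            from .catalog import _squeeze_into_channel
            _squeeze_into_channel(conf, p, channel, seed)
        traj = simulate(conf, p, channel, duration=t_eq1 - t_eq0,
                        sample_interval=plan.sample_interval, seed=seed + 1,
                        equilibration=t_eq0)
        trajs.append(traj)
        axes.append(_bulk_axis(rng))
        if check_topology and conf.n_rings == 2 and k % 7 == 0:
            found = topology.identify_link_type(conf)
            expected = "0_1^2" if link == "trivial_deadlock" else link
            if found != expected:
                audit_ok = False
                logger.warning("topology audit failed: %s -> %s", link, found)

    last_k = max(1, min(5, min(t.n_frames for t in trajs)))
    rg, rg_sem = equilibrium_average(trajs, radius_of_gyration, last_k=last_k)
    span_obs = [
        (lambda c, a=axes[i]: longitudinal_span(c, axis=a if bulk else None))
        for i in range(len(trajs))]
    spans = []
    for traj, obs in zip(trajs, span_obs):
        vals = [obs(traj.conformation(i))
                for i in range(traj.n_frames - last_k, traj.n_frames)]
        spans.append(np.mean(vals))
    span = float(np.mean(spans))
    span_sem = float(np.std(spans, ddof=1) / math.sqrt(len(spans)))

    # physical link length on the last samples (two-ring systems only)
    ells = []
    if trajs[0].ring_of_bead.max() == 2 and link not in ("trivial_deadlock",):
        for traj in trajs:
            for i in range(max(0, traj.n_frames - 2), traj.n_frames,
                           plan.ell_lk_stride or 1):
                pl = topology.locate_physical_link(traj.conformation(i))
                if pl is not None:
                    ells.append(pl.ell_lk)
    ell = float(np.mean(ells)) if ells else float("nan")
    ell_sem = (float(np.std(ells, ddof=1) / math.sqrt(len(ells)))
               if len(ells) > 1 else float("nan"))

    # equilibration diagnostic on the span trace
    half_flags = []
    for traj, obs in zip(trajs, span_obs):
        v = np.array([obs(traj.conformation(i)) for i in range(traj.n_frames)])
        half_flags.append(v[: traj.n_frames // 2].mean()
                          - v[traj.n_frames // 2:].mean())
    drift = float(np.mean(half_flags))
    drift_sem = float(np.std(half_flags, ddof=1)
                      / math.sqrt(len(half_flags))) if len(half_flags) > 1 else 0.0
    equilibrated = abs(drift) <= max(3 * drift_sem, 0.05 * span)

    return {"link": link, "diameter": D, "n_trajectories": len(trajs),
            "rg": rg, "rg_sem": rg_sem, "span": span, "span_sem": span_sem,
            "ell_lk": ell, "ell_lk_sem": ell_sem,
            "equilibrated": equilibrated, "topology_audit_ok": audit_ok}


# ---------------------------------------------------------------------------
# Out-of-equilibrium relaxation
# ---------------------------------------------------------------------------

def run_relaxation_study(plan: ExperimentPlan,
                         params: Optional[ModelParams] = None,
                         equilibrium_table: Optional[pd.DataFrame] = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Relaxation of span and linked-portion length from stretched states.

    For each (link, D): stretched states are prepared under tension
    (t = 0 is the instant the pulling force is switched off), ensembles
    of relaxation trajectories are collected, and tau_s / tau_LK are
    extracted from the standardized curves via the 0.02-cutoff integral.
    Returns (summary table, curves dict) where curves maps
    (link, D) -> {t, f_span, f_ell}.
    """
    plan = plan.scaled()
    if plan.stretch_force <= 0:
        raise ProtocolError("relaxation study requires a nonzero stretch force")
    p = _params_for(plan, params)
    eq = equilibrium_table
    rows = []
    curves = {}
    for link in plan.link_ids:
        for D in plan.channel_diameters:
            row, crv = _relaxation_condition(plan, p, link, D, eq)
            rows.append(row)
            curves[(link, D)] = crv
    return pd.DataFrame(rows), curves


def _stretched_ensemble(plan, p, link, rng) -> list[Conformation]:
    protocol = StretchProtocol(force_magnitude=plan.stretch_force,
                               prep_diameter=plan.prep_diameter,
                               prep_duration=plan.prep_duration)
    confs, diag = prepare_stretched(link, protocol, p, rng,
                                    n_conformations=plan.n_trajectories,
                                    check_topology=False)
    if not all(diag["stationary"]):
        logger.warning("%d/%d preparations flagged non-stationary for %s",
                       sum(not s for s in diag["stationary"]),
                       len(confs), link)
    return confs


def _single_ring_stretched(plan, p, rng, n) -> list[Conformation]:
    """Stretched single 2N ring: prepared by pulling two opposite beads."""
    from .catalog import single_ring_conformation, _squeeze_into_channel
    out = []
    channel = ChannelSpec.for_rings(plan.prep_diameter, 2 * plan.n_beads,
                                    p.sigma)
    for k in range(n):
        seed = int(rng.integers(2 ** 31 - 1))
        conf = single_ring_conformation(2 * plan.n_beads)
        _orient_along_x(conf)
        conf.velocities = maxwell_velocities(conf.n_beads, p,
                                             np.random.default_rng(seed))
        _squeeze_into_channel(conf, p, channel, seed)
        prot = StretchProtocol(force_magnitude=plan.stretch_force,
                               prep_diameter=plan.prep_diameter,
                               prep_duration=plan.prep_duration)
        _simulate_pulled_ring(conf, p, channel, prot, seed)
        out.append(conf.copy())
    return out


def _simulate_pulled_ring(conf, p, channel, prot, seed):
    """Tension-equilibrate a single ring pulled at beads 0 and n/2."""
    from . import _kernels
    n_steps = int(round(prot.prep_duration / p.dt))
    ext = np.zeros_like(conf.positions)
    ext[0, 0] = -prot.force_magnitude
    ext[conf.n_beads // 2, 0] = +prot.force_magnitude
    _kernels.seed_rng(seed % 2 ** 32)
    samples = np.empty((0, conf.n_beads, 3))
    status, _ = _kernels.run_langevin(
        conf.positions, conf.velocities, conf.bonds(), conf.angles(),
        p.epsilon, p.sigma, p.fene_k, p.fene_r0, p.kappa,
        channel.diameter, channel.period_x, ext, p.mass, p.gamma,
        p.temperature, p.dt, n_steps, 0, samples)
    if status != 0:
        raise ProtocolError(f"single-ring preparation failed (status {status})")


def _relaxation_condition(plan, p, link, D, eq_table):
    bulk = math.isinf(D)
    channel = _channel_for(plan, D, p)
    rng = np.random.default_rng(plan.seed + 17 * _stable_stream(link, D))
    single = link == "single_ring_2N"
    if single:
        starts = _single_ring_stretched(plan, p, rng, plan.n_trajectories)
    else:
        starts = _stretched_ensemble(plan, p, link, rng)

    # record t = 0 values before the runs advance the conformations
    span0 = [longitudinal_span(c) for c in starts]
    ell0 = []
    if not single:
        for c in starts:
            pl = topology.locate_physical_link(c)
            ell0.append(pl.ell_lk if pl is not None else np.nan)

    trajs = []
    for conf in starts:
        seed = int(rng.integers(2 ** 31 - 1))
        traj = simulate(conf, p, channel, duration=plan.duration,
                        sample_interval=plan.sample_interval, seed=seed)
        trajs.append(traj)

    # equilibrium means: from the supplied statics table if present,
    # otherwise from the tails of these trajectories
    span_eq, ell_eq = _equilibrium_refs(eq_table, link, D, trajs, plan)

    span_series = ObservableSeries.from_trajectories(
        trajs, longitudinal_span, span_eq, initial_values=span0, label="s")
    try:
        res_s = relaxation_time(span_series)
        row = {"link": link, "diameter": D, "tau_s": res_s.tau_A,
               "tau_s_censored": res_s.censored, "span_eq": span_eq}
        crv = {"t": span_series.times, "f_span": span_series.standardized}
    except CensoredDataError:
        row = {"link": link, "diameter": D, "tau_s": float("nan"),
               "tau_s_censored": True, "span_eq": span_eq}
        crv = {"t": span_series.times,
               "f_span": np.full(span_series.times.shape, np.nan)}

    if not single:
        def ell_of(c):
            pl = topology.locate_physical_link(c)
            return pl.ell_lk if pl is not None else np.nan
        nt = min(t.n_frames for t in trajs)
        idx = range(0, nt, max(1, plan.ell_lk_stride))
        vals = np.array([[ell_of(t.conformation(i)) for i in idx]
                         for t in trajs])
        times = trajs[0].times[list(idx)]
        ell_series = ObservableSeries(times, np.nanmean(vals, axis=0),
                                      ell_eq, float(np.nanmean(ell0)),
                                      label="ell_LK")
        try:
            res_l = relaxation_time(ell_series)
            row.update({"tau_lk": res_l.tau_A,
                        "tau_lk_censored": res_l.censored, "ell_eq": ell_eq})
            crv.update({"t_ell": ell_series.times,
                        "f_ell": ell_series.standardized})
        except CensoredDataError:
            row.update({"tau_lk": float("nan"), "tau_lk_censored": True,
                        "ell_eq": ell_eq})
            crv.update({"t_ell": ell_series.times,
                        "f_ell": np.full(ell_series.times.shape, np.nan)})
    return row, crv


def _equilibrium_refs(eq_table, link, D, trajs, plan):
    if eq_table is not None:
        sel = eq_table[(eq_table["link"] == link)
                       & (eq_table["diameter"] == D)]
        if len(sel) == 1:
            return float(sel["span"].iloc[0]), float(sel["ell_lk"].iloc[0])
    # fall back: tail averages of the relaxation ensembles themselves
    span_eq, _ = equilibrium_average(trajs, longitudinal_span)
    ells = []
    if trajs[0].ring_of_bead.max() == 2:
        for traj in trajs:
            pl = topology.locate_physical_link(
                traj.conformation(traj.n_frames - 1))
            if pl is not None:
                ells.append(pl.ell_lk)
    return span_eq, float(np.mean(ells)) if ells else float("nan")


# ---------------------------------------------------------------------------
# Eyelets and deadlocks
# ---------------------------------------------------------------------------

def run_entanglement_study(plan: ExperimentPlan,
                           params: Optional[ModelParams] = None,
                           eyelet_link: str = "6_1^2",
                           n_projections: int = 21,
                           parts: tuple[str, ...] = ("eyelet", "deadlock")
                           ) -> tuple[pd.DataFrame, dict]:
    """Geometric-entanglement experiments.

    Eyelet part: time series of span, ell_LK and the average crossing
    number <c> (over ``n_projections`` random projections) for plain vs
    eyelet-decorated stretched states of ``eyelet_link`` at each D.
    Deadlock part: survival S(t) of the deadlocked unlinked pair per D
    and the fitted lifetime tau_surv.

    Returns (summary table, curves) with curves keyed by
    (kind, link, D) -> dict of time series.
    """
    plan = plan.scaled()
    p = _params_for(plan, params)
    rows = []
    curves = {}
    for D in plan.channel_diameters:
        if "eyelet" in parts:
            for decorated in (False, True):
                row, crv = _eyelet_condition(plan, p, eyelet_link, D,
                                             decorated, n_projections)
                rows.append(row)
                curves[("eyelet" if decorated else "plain",
                        eyelet_link, D)] = crv
        if "deadlock" in parts:
            row, crv = _deadlock_condition(plan, p, D)
            rows.append(row)
            curves[("deadlock", "trivial_deadlock", D)] = crv
    return pd.DataFrame(rows), curves


def _eyelet_condition(plan, p, link, D, decorated, n_projections):
    channel = _channel_for(plan, D, p)
    rng = np.random.default_rng(plan.seed + (31 if decorated else 13)
                                + _stable_stream("eyelet", D))
    protocol = StretchProtocol(
        force_magnitude=plan.stretch_force,
        prep_diameter=plan.prep_diameter,
        prep_duration=(plan.eyelet_prep_duration if decorated
                       else plan.prep_duration))
    starts = []
    eyelet_start = add_eyelet(catalog_conformation(link, plan.n_beads))         if decorated else None
    while len(starts) < plan.n_trajectories:
        confs, _ = prepare_stretched(link, protocol, p, rng,
                                     n_conformations=1,
                                     start=eyelet_start,
                                     check_topology=False)
        starts.append(confs[0])

    trajs = [simulate(c, p, channel, duration=plan.duration,
                      sample_interval=plan.sample_interval,
                      seed=int(rng.integers(2 ** 31 - 1)))
             for c in starts]

    nt = min(t.n_frames for t in trajs)
    times = trajs[0].times[:nt]
    span = np.array([[longitudinal_span(t.conformation(i))
                      for i in range(nt)] for t in trajs]).mean(axis=0)
    acn_rng = np.random.default_rng(plan.seed + 555)
    stride = max(1, plan.ell_lk_stride)
    idx = list(range(0, nt, stride))
    acn = np.array([[topology.average_crossing_number(
        t.conformation(i), n_directions=n_projections, rng=acn_rng)
        for i in idx] for t in trajs]).mean(axis=0)
    ell = np.array([[_ell_or_nan(t.conformation(i)) for i in idx]
                    for t in trajs])
    ell = np.nanmean(ell, axis=0)
    crv = {"t": times, "span": span, "t_sub": times[idx], "acn": acn,
           "ell": ell}
    row = {"kind": "eyelet" if decorated else "plain", "link": link,
           "diameter": D,
           "span_min_time": float(times[int(np.argmin(span))]),
           "acn_max_time": float(times[idx][int(np.argmax(acn))]),
           "acn_initial": float(acn[0]), "acn_max": float(acn.max()),
           "span_initial": float(span[0])}
    return row, crv


def _ell_or_nan(conf):
    pl = topology.locate_physical_link(conf)
    return pl.ell_lk if pl is not None else np.nan


def _deadlock_condition(plan, p, D):
    """Deadlock survival at one channel width.

    The deadlocked pair is built taut by construction; even a short
    pulling pulse at f = 20 k_BT/sigma slides the hooks apart at these
    reduced sizes, so preparation is force-free: settle, close the
    channel to the *study* width and equilibrate briefly
    (``plan.deadlock_prep_duration``).
    """
    from .catalog import (_orient_along_x, _squeeze_into_channel,
                          deadlock_conformation)
    from .dynamics import maxwell_velocities, soft_relax

    channel = _channel_for(plan, D, p)
    rng = np.random.default_rng(plan.seed + 7177 + _stable_stream("deadlock", D))
    starts = []
    for k in range(plan.n_trajectories):
        seed = int(rng.integers(2 ** 31 - 1))
        conf = deadlock_conformation(plan.n_beads)
        _orient_along_x(conf)
        conf.velocities = maxwell_velocities(conf.n_beads, p,
                                             np.random.default_rng(seed))
        soft_relax(conf, p, ChannelSpec.bulk(), seed=seed + 3)
        _squeeze_into_channel(conf, p, channel, seed)
        simulate(conf, p, channel, duration=plan.deadlock_prep_duration,
                 sample_interval=plan.deadlock_prep_duration, seed=seed + 7)
        starts.append(conf)
    # advance chunk-wise and stop once a trajectory becomes separable
    # (disengagement is absorbing, so the remainder need not be simulated)
    nt = int(round(plan.duration / plan.sample_interval))
    times = (np.arange(1, nt + 1)) * plan.sample_interval
    flags = np.zeros((len(starts), nt), dtype=bool)
    for k, conf in enumerate(starts):
        seed = int(rng.integers(2 ** 31 - 1))
        for i in range(nt):
            simulate(conf, p, channel, duration=plan.sample_interval,
                     sample_interval=plan.sample_interval, seed=seed + i)
            if topology.is_linearly_separable(conf.ring_positions(1),
                                              conf.ring_positions(2)):
                flags[k, i:] = True
                break
    res = survival_analysis(flags, times,
                            definition=plan.survival_definition)
    row = {"kind": "deadlock", "link": "trivial_deadlock", "diameter": D,
           "tau_surv": res.tau_surv, "tau_surv_censored": res.censored,
           "n_censored": res.n_censored,
           "disengaged_fraction": float(1.0 - res.survival[-1])}
    crv = {"t": res.times, "survival": res.survival}
    return row, crv


# ---------------------------------------------------------------------------
# Persistence and serialization helpers
# ---------------------------------------------------------------------------

def save_results(out_dir, tables: dict[str, pd.DataFrame],
                 summary: Optional[dict] = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if summary is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
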