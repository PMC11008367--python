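"""Catalog of interlocked-ring topologies and initial-state preparation.

The repertoire covers four families of two-component links named in
Rolfsen notation (crossing number n_c, enumeration subscript, superscript
2 for the component count):

* torus links 2_1^2 (Hopf), 4_1^2 (Solomon), 6_1^2 (Star of David):
  built parametrically as (2, n_c) windings on a common torus; every
  minimal-diagram crossing is mutual;
* twist-like links 5_1^2 (Whitehead), 6_3^2, 7_3^2: four mutual crossings
  plus 1, 2, 3 self-crossings in the clasp; realized as rational 4-plats
  C(2, k, 2);
* links with exactly one self-crossing 5_1^2, 7_1^2, 9_1^2: rational
  4-plats C(2m, 1, 2) -- note 5_1^2 belongs to both this and the previous
  family;
* all-mutual non-torus links 6_2^2, 8_2^2: rational 4-plats C(1, 2, k).

Plus two special systems: a single unknotted ring of doubled contour
length (2N beads), and a pair of *unlinked* rings wound into the
double-hooked deadlock clasp (braid closure of sigma^2 sigma^-2: its
mutual crossings are reminiscent of the Solomon link, but the braid is
trivial, so the rings are topologically free).

Every builder output is validated by round-tripping through
:func:`linkedrings.topology.identify_link_type`; the canonical projection
of each ideal embedding is a reduced alternating diagram, hence of minimal
crossing number (Tait), and supplies the packaged crossing lists.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import braidgeom, topology
from .dynamics import (Conformation, maxwell_velocities, simulate,
                       soft_relax)
from .errors import CatalogError, ProtocolError
from .params import ChannelSpec, ModelParams, StretchProtocol

__all__ = [
    "LinkID", "LinkDiagram", "CATALOG", "link_ids", "family_of",
    "torus_link_conformation", "catalog_conformation", "minimal_diagram",
    "reference_fingerprints", "add_eyelet", "prepare_stretched",
    "deadlock_conformation", "single_ring_conformation", "ideal_curves",
    "place_in_channel",
]

logger = logging.getLogger(__name__)

BOND_TARGET = 0.97        # FENE+WCA equilibrium spacing [sigma]
_LANE_GAP_SIGMA = 1.7     # transverse lane spacing of plat templates [sigma]


@dataclass(frozen=True)
class LinkID:
    """Catalog topology identifier.

    ``rolfsen_name`` is of the form ``c_k^2`` for the linked pairs, or one
    of the special labels ``single_ring_2N`` / ``trivial_deadlock`` /
    ``0_1^2`` (split trivial link).
    """
    rolfsen_name: str
    family: str     # torus | twist_like | one_self_crossing | other | special

    @property
    def n_c(self) -> int:
        if self.family == "special":
            return 0
        return int(self.rolfsen_name.split("_")[0])

    def __str__(self) -> str:
        return self.rolfsen_name


# name -> (family, builder kind, builder argument, (n_self, n_mutual))
_TABLE: dict[str, tuple[str, str, object, tuple[int, int]]] = {
    "2_1^2": ("torus", "torus", 2, (0, 2)),
    "4_1^2": ("torus", "torus", 4, (0, 4)),
    "6_1^2": ("torus", "torus", 6, (0, 6)),
    "5_1^2": ("twist_like", "rational", (2, 1, 2), (1, 4)),
    "6_3^2": ("twist_like", "rational", (2, 2, 2), (2, 4)),
    "7_3^2": ("twist_like", "rational", (2, 3, 2), (3, 4)),
    "7_1^2": ("one_self_crossing", "rational", (4, 1, 2), (1, 6)),
    "9_1^2": ("one_self_crossing", "rational", (6, 1, 2), (1, 8)),
    "6_2^2": ("other", "rational", (1, 2, 3), (0, 6)),
    "8_2^2": ("other", "rational", (1, 2, 5), (0, 8)),
}

#: Family groupings as displayed in the repertoire (5_1^2 appears twice).
FAMILIES = {
    "torus": ("2_1^2", "4_1^2", "6_1^2"),
    "twist_like": ("5_1^2", "6_3^2", "7_3^2"),
    "one_self_crossing": ("5_1^2", "7_1^2", "9_1^2"),
    "other": ("6_2^2", "8_2^2"),
}

SPECIAL = ("single_ring_2N", "trivial_deadlock")

CATALOG: dict[str, LinkID] = {
    **{name: LinkID(name, fam) for name, (fam, _, _, _) in _TABLE.items()},
    "single_ring_2N": LinkID("single_ring_2N", "special"),
    "trivial_deadlock": LinkID("trivial_deadlock", "special"),
    "0_1^2": LinkID("0_1^2", "special"),
}


def link_ids(include_special: bool = False) -> list[str]:
    names = list(_TABLE)
    if include_special:
        names += list(SPECIAL)
    return names


def family_of(name: str) -> str:
    if name not in CATALOG:
        raise CatalogError(f"unknown topology {name!r}")
    return CATALOG[name].family


@dataclass
class LinkDiagram:
    """Minimal planar diagram of a catalog topology.

    ``crossings`` records (over_arc, under_in_arc, under_out_arc, sign,
    comp_over, comp_under) per crossing, with Wirtinger arc indices from
    the canonical projection.
    """
    name: str
    crossings: list[tuple[int, int, int, int, int, int]]

    @property
    def n_c(self) -> int:
        return len(self.crossings)

    @property
    def n_self(self) -> int:
        return sum(1 for c in self.crossings if c[4] == c[5])

    @property
    def n_mutual(self) -> int:
        return sum(1 for c in self.crossings if c[4] != c[5])


# ---------------------------------------------------------------------------
# Ideal embeddings
# ---------------------------------------------------------------------------

_CANONICAL_DIRECTION = np.array([0.013, 0.007, 1.0])  # generic near-z


def _torus_curves(q: int, n_pts: int = 400) -> list[np.ndarray]:
    """(2, q) torus link wound on a common torus (unit major radius)."""
    r_minor = 0.45
    out = []
    for k in (0, 1):
        th = np.linspace(0.0, 2 * np.pi, n_pts, endpoint=False)
        psi = 0.5 * q * th + np.pi * k
        rad = 1.0 + r_minor * np.cos(psi)
        out.append(np.column_stack([rad * np.cos(th), rad * np.sin(th),
                                    r_minor * np.sin(psi)]))
    return out


@lru_cache(maxsize=None)
def ideal_curves(name: str) -> tuple[np.ndarray, ...]:
    """Ideal (unscaled) closed curves realizing a catalog topology."""
    if name == "0_1^2":
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = np.column_stack([np.cos(th), np.sin(th), 0 * th])
        return (ring, ring + np.array([4.0, 0.0, 0.0]))
    if name == "trivial_deadlock":
        tmpl = braidgeom.BraidTemplate(2, ((0, 2, 1), (0, 2, -1)), "braid")
        return tuple(braidgeom.build_template(tmpl))
    if name == "single_ring_2N":
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        return (np.column_stack([np.cos(th), np.sin(th), 0 * th]),)
    if name not in _TABLE:
        raise CatalogError(f"unknown topology {name!r}")
    _, kind, arg, _ = _TABLE[name]
    if kind == "torus":
        return tuple(_torus_curves(int(arg)))  # type: ignore[arg-type]
    return tuple(braidgeom.build_template(
        braidgeom.rational_template(arg)))    # type: ignore[arg-type]


def _curve_length(curve: np.ndarray) -> float:
    closed = np.vstack([curve, curve[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _scale_to_beads(curves: Sequence[np.ndarray], N: int,
                    transverse_gap: float = _LANE_GAP_SIGMA,
                    isotropic: bool = False) -> list[np.ndarray]:
    """Scale ideal curves so each resampled N-bead ring has bond lengths in
    the FENE comfort range.

    Plat/braid templates are scaled anisotropically: the transverse (y, z)
    scale fixes strand gaps at ``transverse_gap`` sigma and the
    longitudinal scale is solved so the longest component matches the
    contour budget N * BOND_TARGET.  Parametric torus curves are scaled
    isotropically.
    """
    budget = N * BOND_TARGET
    if isotropic:
        s = budget / max(_curve_length(c) for c in curves)
        return [c * s for c in curves]
    st = transverse_gap / braidgeom.LANE_GAP

    def max_len(sx: float) -> float:
        return max(_curve_length(c * np.array([sx, st, st])) for c in curves)

    lo, hi = 1e-3, 1e3
    if max_len(lo) > budget:
        raise CatalogError(
            f"N = {N} too small to realize this topology without overstretch")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if max_len(mid) > budget:
            hi = mid
        else:
            lo = mid
    sx = math.sqrt(lo * hi)
    # successive turns of a twist helix are 2*TWIST_LEN*sx apart along x;
    # below ~1 sigma they would overlap sterically
    if sx * 2 * braidgeom.TWIST_LEN < 0.96:
        raise CatalogError(
            f"N = {N} too small to realize this topology without overstretch")
    return [c * np.array([sx, st, st]) for c in curves]


def _to_conformation(curves: Sequence[np.ndarray], N: int) -> Conformation:
    beads = [braidgeom.resample_closed(c, N) for c in curves]
    pos = np.vstack(beads)
    rings = np.concatenate([np.full(b.shape[0], i + 1, dtype=np.int64)
                            for i, b in enumerate(beads)])
    conf = Conformation(pos, rings)
    conf.recenter()
    return conf


def torus_link_conformation(n_c: int, N: int,
                            scale: Optional[float] = None) -> Conformation:
    """Two rings winding on a common torus, realizing the (2, n_c) link.

    ``n_c`` must be even (odd windings close into a single component,
    i.e. a torus knot, not a 2-component link).
    """
    if n_c % 2 or n_c < 2:
        raise CatalogError("(2, n_c) torus links require even n_c >= 2")
    curves = _torus_curves(n_c)
    if scale is not None:
        curves = [c * scale for c in curves]
    else:
        curves = _scale_to_beads(curves, N, isotropic=True)
    conf = _to_conformation(curves, N)
    _check_feasible(conf)
    return conf


def _check_feasible(conf: Conformation, min_gap: float = 0.55) -> None:
    """Reject builds with overstretched bonds or deep steric overlaps."""
    from . import _kernels
    bonds = conf.bonds()
    d = np.linalg.norm(conf.positions[bonds[:, 0]] - conf.positions[bonds[:, 1]], axis=1)
    if d.max() >= 1.35:
        raise CatalogError(f"bond length {d.max():.2f} beyond FENE comfort range")
    if conf.n_rings == 2:
        gap = _kernels.min_segment_gap(conf.ring_positions(1),
                                       conf.ring_positions(2))
        if gap < min_gap:
            raise CatalogError(f"inter-ring gap {gap:.2f} sigma too small")


def single_ring_conformation(n_beads: int) -> Conformation:
    """A single unknotted circular ring of ``n_beads`` beads."""
    radius = n_beads * BOND_TARGET / (2 * np.pi)
    th = np.linspace(0, 2 * np.pi, n_beads, endpoint=False)
    pos = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                           np.zeros_like(th)])
    return Conformation(pos, np.ones(n_beads, dtype=np.int64))


def deadlock_conformation(N: int) -> Conformation:
    """Two unlinked rings interleaved in the taut double-hooked clasp.

    Constructed directly in the taut stretched geometry (arm lengths
    solved per ring so bonds sit at the FENE equilibrium spacing): the
    wound-then-unwound clasp is topologically trivial but geometrically
    hooked, and is not linearly separable until one hook slides out.
    """
    budget = N * BOND_TARGET

    def ring_length(which: int, arm: float) -> float:
        curves = braidgeom.taut_deadlock_pair(arm, arm)
        return _curve_length(curves[which])

    arms = []
    for which in (0, 1):
        lo, hi = 4.0, 400.0
        if ring_length(which, lo) > budget:
            raise CatalogError(f"N = {N} too small for the deadlock clasp")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ring_length(which, mid) > budget:
                hi = mid
            else:
                lo = mid
        arms.append(0.5 * (lo + hi))
    curves = braidgeom.taut_deadlock_pair(arms[0], arms[1])
    conf = _to_conformation(curves, N)
    _check_feasible(conf)
    return conf


def catalog_conformation(link_id: str | LinkID, N: int,
                         rng: Optional[np.random.Generator] = None) -> Conformation:
    """Valid conformation realizing a catalog topology.

    ``single_ring_2N`` returns one unknotted ring of 2N beads;
    ``trivial_deadlock`` the unlinked double-hooked pair; every other
    label builds the ideal embedding scaled to N beads per ring.
    """
    name = str(link_id)
    if name == "single_ring_2N":
        return single_ring_conformation(2 * N)
    if name == "trivial_deadlock":
        return deadlock_conformation(N)
    if name == "0_1^2":
        radius = N * BOND_TARGET / (2 * np.pi)
        th = np.linspace(0, 2 * np.pi, N, endpoint=False)
        ring = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                np.zeros_like(th)])
        pos = np.vstack([ring, ring + np.array([3 * radius, 0, 0])])
        return Conformation(pos, np.repeat([1, 2], N))
    if name not in _TABLE:
        raise CatalogError(f"unknown topology {name!r}")
    fam, kind, arg, _ = _TABLE[name]
    if kind == "torus":
        return torus_link_conformation(int(arg), N)  # type: ignore[arg-type]
    if N == 120:
        fixture = _conformation_path(name)
        if fixture.exists():
            from .io import read_xyz
            return read_xyz(fixture)
    curves = _scale_to_beads(list(ideal_curves(name)), N)
    conf = _to_conformation(curves, N)
    _check_feasible(conf)
    return conf


# ---------------------------------------------------------------------------
# Minimal diagrams and reference fingerprints
# ---------------------------------------------------------------------------

def _diagram_from_curves(name: str, curves) -> LinkDiagram:
    cset = topology.projected_crossings(curves, _CANONICAL_DIRECTION)
    arcs = topology._diagram_arcs([np.asarray(c) for c in curves], cset)
    if arcs is None:
        raise CatalogError("split canonical projection")
    _, rows = arcs
    crossings = []
    for (o, i, j, sign), c in zip(rows, cset.crossings):
        crossings.append((o, i, j, sign, c.comp_over, c.comp_under))
    return LinkDiagram(name=name, crossings=crossings)


def _diagram_path(name: str) -> Path:
    safe = name.replace("^", "c").replace("_", "-")
    return Path(str(resources.files("linkedrings") / "data" / "diagrams" /
                    f"{safe}.txt"))


def _conformation_path(name: str) -> Path:
    safe = name.replace("^", "c").replace("_", "-")
    return Path(str(resources.files("linkedrings") / "data" / "conformations" /
                    f"{safe}_N120.xyz"))


def minimal_diagram(link_id: str | LinkID) -> LinkDiagram:
    """Packaged minimal planar diagram of a two-component catalog topology."""
    name = str(link_id)
    if name in SPECIAL or name == "0_1^2":
        raise CatalogError(f"{name} has no packaged minimal diagram")
    if name not in _TABLE:
        raise CatalogError(f"unknown topology {name!r}")
    path = _diagram_path(name)
    if path.exists():
        return _load_diagram(name, path)
    return _diagram_from_curves(name, list(ideal_curves(name)))


def _load_diagram(name: str, path: Path) -> LinkDiagram:
    crossings = []
    for line in path.read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        o, i, j, sign, co, cu = (int(v) for v in line.split())
        crossings.append((o, i, j, sign, co, cu))
    return LinkDiagram(name=name, crossings=crossings)


def save_diagram(diagram: LinkDiagram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# minimal diagram of {diagram.name}: one crossing per "
                 "line\n# over_arc under_in_arc under_out_arc sign "
                 "comp_over comp_under\n")
        for c in diagram.crossings:
            fh.write(" ".join(str(v) for v in c) + "\n")


@lru_cache(maxsize=1)
def reference_fingerprints() -> dict[str, topology.LinkFingerprint]:
    """Invariant fingerprints of all catalog topologies (from the ideal
    embeddings), used by :func:`linkedrings.topology.identify_link_type`."""
    out: dict[str, topology.LinkFingerprint] = {}
    for name in link_ids():
        curves = ideal_curves(name)
        out[name] = topology.alexander_fingerprint(
            list(curves), rng=np.random.default_rng(99))
    out["0_1^2"] = topology.LinkFingerprint(0, tuple(0.0 for _ in
                                                     topology._EVAL_ANGLES))
    return out


# ---------------------------------------------------------------------------
# Stretched-state preparation
# ---------------------------------------------------------------------------

def _orient_along_x(conf: Conformation) -> Conformation:
    """Rotate so the conformation's longest principal axis lies along x."""
    pos = conf.positions - conf.positions.mean(axis=0)
    cov = pos.T @ pos
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    conf.positions = pos @ axes
    return conf


def _squeeze_into_channel(conf: Conformation, params: ModelParams,
                          target: ChannelSpec, seed: int,
                          stage_time: float = 10.0,
                          dt: Optional[float] = None,
                          protocol: Optional[StretchProtocol] = None) -> ChannelSpec:
    """Progressively shrink the channel until the target diameter fits.

    Per-step displacements are capped during the stages (the wall sweeps
    beads inward, which can otherwise produce impulsive forces), and an
    optional pulling protocol stays active so that threaded decorations
    are entrenched rather than lost while the channel closes in.
    """
    if dt is not None:
        params = params.with_(dt=dt)
    conf.positions[:, 1:] -= conf.positions[:, 1:].mean(axis=0)
    rho = np.hypot(conf.positions[:, 1], conf.positions[:, 2]).max()
    d = max(2 * rho + 3.0, target.diameter)
    for stage in range(300):
        if d <= target.diameter * 1.001:
            break
        # shrink only as far as the current bead envelope safely allows
        rho = np.hypot(conf.positions[:, 1], conf.positions[:, 2]).max()
        # shrink by at most 10% per stage and never below the
        # current bead envelope plus a safe gap
        d = max(target.diameter, min(max(0.9 * d, 2 * rho + 1.0),
                                     2 * rho + 1.9))
        chan = ChannelSpec(diameter=d, period_x=target.period_x)
        simulate(conf, params, chan, duration=stage_time,
                 sample_interval=stage_time, seed=seed + 7919 * stage,
                 protocol=protocol, max_disp=0.05)
    else:
        raise ProtocolError("channel squeeze did not converge")
    return target


def place_in_channel(conf: Conformation, params: ModelParams,
                     channel: ChannelSpec, seed: int = 0) -> Conformation:
    """Orient a conformation along the channel axis and insert it.

    The longest principal axis is aligned with x, velocities are drawn at
    the target temperature, compressed bonds are healed by a capped
    push-off, and the channel is closed in stages down to the target
    diameter (idealized embeddings are usually wider than a narrow
    channel).  In bulk only the push-off is applied.  Operates in place
    and returns the conformation.
    """
    _orient_along_x(conf)
    conf.velocities = maxwell_velocities(conf.n_beads, params,
                                         np.random.default_rng(seed))
    soft_relax(conf, params, ChannelSpec.bulk(), seed=seed + 3)
    if not channel.is_bulk:
        _squeeze_into_channel(conf, params, channel, seed)
    return conf


def prepare_stretched(link_id: str | LinkID, protocol: StretchProtocol,
                      params: ModelParams, rng: np.random.Generator,
                      n_conformations: int = 1,
                      start: Optional[Conformation] = None,
                      check_topology: bool = True,
                      squeeze_dt: Optional[float] = None
                      ) -> tuple[list[Conformation], dict]:
    """Tension-equilibrated stretched conformations of a catalog link.

    Following the preparation protocol, the link is confined in a narrow
    channel (``protocol.prep_diameter``), one bead per ring is pulled with
    constant force f in opposite longitudinal directions, and the system
    is equilibrated under tension for ``protocol.prep_duration``.  Each
    returned conformation comes from an independently seeded preparation.
    A stationarity diagnostic (first vs second half of the longitudinal
    span trace during tension equilibration) is returned alongside.
    """
    from .observables import longitudinal_span

    name = str(link_id)
    target = ChannelSpec.for_rings(protocol.prep_diameter,
                                   2 * params.N, params.sigma)
    confs = []
    diagnostics = {"span_drift": [], "stationary": []}
    ref_type = None
    for k in range(n_conformations):
        seed = int(rng.integers(2 ** 31 - 1))
        conf = (start.copy() if start is not None
                else catalog_conformation(name, params.N))
        _orient_along_x(conf)
        conf.velocities = maxwell_velocities(conf.n_beads, params,
                                             np.random.default_rng(seed))
        soft_relax(conf, params, ChannelSpec.bulk(), seed=seed + 3)
        _squeeze_into_channel(conf, params, target, seed, dt=squeeze_dt)
        traj = simulate(conf, params, target,
                        duration=protocol.prep_duration,
                        sample_interval=max(params.dt * 10,
                                            protocol.prep_duration / 50),
                        seed=seed + 1, protocol=protocol)
        spans = np.array([longitudinal_span(traj.conformation(i))
                          for i in range(traj.n_frames)])
        half = len(spans) // 2
        drift = float(spans[half:].mean() - spans[:half].mean())
        sem = float(spans[half:].std(ddof=1) / math.sqrt(max(1, half)))
        diagnostics["span_drift"].append(drift)
        diagnostics["stationary"].append(
            abs(drift) <= max(3 * sem, 0.04 * spans.mean()))
        if check_topology and name in _TABLE:
            if ref_type is None:
                ref_type = name
            found = topology.identify_link_type(conf)
            if found != name:
                raise ProtocolError(
                    f"topology changed during preparation: {found!r}")
        confs.append(conf.copy())
    return confs, diagnostics


# ---------------------------------------------------------------------------
# Eyelets (doubly threaded decorations)
# ---------------------------------------------------------------------------

def add_eyelet(conf: Conformation, check: bool = True) -> Conformation:
    """Fold an external tip inward and thread it through the entangled
    region, returning a taut doubly threaded ("eyelet") initial state.

    The decorated state is constructed directly in the taut stretched
    geometry: the clasp is an antipodal double helix of the two rings'
    winding strands, and the first ring's tip hairpin runs through the
    free core of that winding, folding just past its far end, so the tip
    swaps sides.  Threading a taut clasp is essential: in a loose state
    the hairpin simply retracts along its own tube (the decoration is
    ambient-isotopic to the plain link -- verified via the invariant
    fingerprint), whereas the taut winding pressed onto the hairpin by
    the pulling forces jams it into a long-lived geometric entanglement.
    Supported for torus-family inputs; raises :class:`ProtocolError`
    otherwise.
    """
    if conf.n_rings != 2:
        raise ProtocolError("eyelets require a two-ring conformation")
    name = topology.identify_link_type(conf)
    if name not in _TABLE or _TABLE[name][0] != "torus":
        raise ProtocolError(
            f"eyelet decoration is implemented for torus-family links, "
            f"got {name!r}")
    n_beads = int(conf.ring_indices(1).size)
    q = int(_TABLE[name][2])
    budget = n_beads * BOND_TARGET

    def ring_length(which: int, arm: float) -> float:
        arms = (arm, arm)
        curves = braidgeom.taut_decorated_pair(q, arms[0], arms[1])
        return _curve_length(curves[which])

    arms = []
    for which in (0, 1):
        lo, hi = max(2.0, 0.7 * q) + 1.0, 400.0
        if ring_length(which, lo) > budget:
            raise CatalogError(
                f"N = {n_beads} too small for the threaded decoration")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ring_length(which, mid) > budget:
                hi = mid
            else:
                lo = mid
        arms.append(0.5 * (lo + hi))
    curves = braidgeom.taut_decorated_pair(q, arms[0], arms[1])
    new = _to_conformation(curves, n_beads)
    _check_feasible(new, min_gap=0.5)
    # displacement-capped overdamped push-off for the tight core contacts
    relax_params = ModelParams(N=n_beads)
    new.velocities = maxwell_velocities(new.n_beads, relax_params,
                                        np.random.default_rng(12345))
    soft_relax(new, relax_params, ChannelSpec.bulk(), seed=54321,
               duration=5.0)
    if check:
        after = topology.identify_link_type(new)
        if after != name:
            raise ProtocolError(
                f"eyelet construction altered the topology: {name} -> {after}")
    return new
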