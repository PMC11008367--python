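"""Topological and geometrical entanglement analysis of 3D conformations.

The module provides, for pairs of closed polygonal curves:

* the Gauss linking number, computed either by the discrete Gauss double
  sum (Klenin-Langowski) or by half the signed sum of inter-ring crossings
  in a generic planar projection -- the two routes must agree;
* planar crossing sets (signed, over/under, self vs mutual) for arbitrary
  projection directions, and the average crossing number over directions
  drawn uniformly from the unit sphere;
* an Alexander-polynomial fingerprint, evaluated from the Wirtinger
  presentation of a projected diagram at fixed points on the unit circle.
  The evaluations |D(t)| with |t| = 1 are invariant under the unit
  ambiguity +-t^a of the Alexander matrix minor, mirror-insensitive, and
  together with |Lk| they distinguish all topologies shipped in the
  catalog;
* physical-link localization: the shortest pair of subchains (one per
  ring) whose independent closures reproduce the link type of the whole
  conformation, found bottom-up in summed contour length;
* linear separability of the two rings, decided exactly as convex-hull
  disjointness through a linear feasibility program.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from . import _kernels
from .errors import DegenerateGeometryError

__all__ = [
    "CrossingSet", "PhysicalLink", "gauss_linking_number",
    "projected_crossings", "average_crossing_number", "writhe_fingerprint",
    "alexander_fingerprint", "identify_link_type", "close_subchain",
    "locate_physical_link", "is_linearly_separable", "LinkFingerprint",
]

logger = logging.getLogger(__name__)

#: Unit-circle evaluation angles for the Alexander fingerprint.  t = -1
#: gives (twice) the classical link determinant; the other two are generic
#: points that break remaining degeneracies among the catalog topologies.
_EVAL_ANGLES = (math.pi, 1.0, 2.0)


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

def gauss_linking_number(ring1: np.ndarray, ring2: np.ndarray) -> int:
    """Gauss linking number of two disjoint closed polygonal curves.

    Evaluates the discrete Gauss double sum and rounds; a result far from
    an integer signals (numerically) intersecting segments.
    """
    r1 = np.ascontiguousarray(ring1, dtype=np.float64)
    r2 = np.ascontiguousarray(ring2, dtype=np.float64)
    total = _kernels.gauss_linking_sum(r1, r2)
    nearest = round(total)
    if abs(total - nearest) > 0.2:
        raise DegenerateGeometryError(
            f"Gauss sum {total:.4f} far from integer: curves intersect?")
    return int(nearest)


# ---------------------------------------------------------------------------
# Planar projections and crossing sets
# ---------------------------------------------------------------------------

@dataclass
class Crossing:
    """One transversal crossing in a planar projection."""
    seg_over: int          # global segment index of the over strand
    seg_under: int
    t_over: float          # intersection parameter along the over segment
    t_under: float
    sign: int              # right-handed (tangent_over, tangent_under) sign
    comp_over: int         # component labels (ring ids)
    comp_under: int

    @property
    def is_self(self) -> bool:
        return self.comp_over == self.comp_under


@dataclass
class CrossingSet:
    """All crossings of one planar projection of a conformation."""
    direction: np.ndarray
    crossings: list[Crossing]

    @property
    def count(self) -> int:
        return len(self.crossings)

    @property
    def n_self(self) -> int:
        return sum(1 for c in self.crossings if c.is_self)

    @property
    def n_mutual(self) -> int:
        return sum(1 for c in self.crossings if not c.is_self)

    @property
    def signed_mutual_sum(self) -> int:
        return sum(c.sign for c in self.crossings if not c.is_self)


def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(direction, dtype=np.float64)
    n = np.linalg.norm(w)
    if n == 0:
        raise ValueError("zero projection direction")
    w = w / n
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def _segments(curves: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenated vertices plus per-segment start/end/component arrays."""
    pts, sstart, send, scomp = [], [], [], []
    offset = 0
    for ci, c in enumerate(curves):
        n = c.shape[0]
        pts.append(c)
        for i in range(n):
            sstart.append(offset + i)
            send.append(offset + (i + 1) % n)
            scomp.append(ci)
        offset += n
    return (np.vstack(pts),
            np.asarray(sstart, dtype=np.int64),
            np.asarray(send, dtype=np.int64),
            np.asarray(scomp, dtype=np.int64))


def _curves_of(obj) -> list[np.ndarray]:
    """Accept a Conformation or a sequence of (n, 3) arrays."""
    if hasattr(obj, "rings"):
        return [np.ascontiguousarray(r, dtype=np.float64) for r in obj.rings()]
    return [np.ascontiguousarray(c, dtype=np.float64) for c in obj]


def projected_crossings(conformation, direction: np.ndarray,
                        max_retries: int = 8,
                        _rng: Optional[np.random.Generator] = None) -> CrossingSet:
    """Crossings of the projection perpendicular to ``direction``.

    A degenerate direction (crossing exactly at a vertex, parallel
    segments meeting, equal depths) triggers an automatic small
    perturbation of the direction, logged and repeated up to
    ``max_retries`` times.
    """
    curves = _curves_of(conformation)
    pts, sstart, send, scomp = _segments(curves)
    rng = _rng or np.random.default_rng(0)
    d = np.asarray(direction, dtype=np.float64)
    for attempt in range(max_retries):
        try:
            return _projected_crossings_once(pts, sstart, send, scomp, d)
        except DegenerateGeometryError:
            logger.info("degenerate projection along %s; perturbing", d)
            d = d + rng.normal(scale=1e-4 * (1 + attempt), size=3)
    raise DegenerateGeometryError("projection still degenerate after retries")


def _projected_crossings_once(pts, sstart, send, scomp, direction) -> CrossingSet:
    u, v, w = _orthonormal_frame(direction)
    p2d = np.column_stack([pts @ u, pts @ v])
    depth = pts @ w
    cap = 16 * len(sstart)
    out_a = np.empty(cap, dtype=np.int64)
    out_b = np.empty(cap, dtype=np.int64)
    out_sign = np.empty(cap, dtype=np.int64)
    out_over = np.empty(cap, dtype=np.int64)
    out_ta = np.empty(cap)
    out_tb = np.empty(cap)
    n = _kernels.find_crossings(p2d, depth, sstart, send, scomp,
                                out_a, out_b, out_sign, out_over, out_ta, out_tb)
    if n > cap:
        raise DegenerateGeometryError("crossing buffer overflow")
    crossings = []
    eps = 1e-9
    for k in range(n):
        a, b = int(out_a[k]), int(out_b[k])
        ta, tb = float(out_ta[k]), float(out_tb[k])
        if min(ta, 1 - ta, tb, 1 - tb) < eps:
            raise DegenerateGeometryError("crossing at a vertex")
        if out_over[k]:
            crossings.append(Crossing(a, b, ta, tb, int(out_sign[k]),
                                      int(scomp[a]), int(scomp[b])))
        else:
            crossings.append(Crossing(b, a, tb, ta, int(out_sign[k]),
                                      int(scomp[b]), int(scomp[a])))
    return CrossingSet(direction=np.asarray(direction, dtype=np.float64),
                       crossings=crossings)


def sphere_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Directions drawn uniformly from the unit sphere."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def average_crossing_number(conformation, n_directions: int = 21,
                            rng: Optional[np.random.Generator] = None) -> float:
    """Mean projected crossing count over random projection planes.

    The plane normals are picked uniformly from the unit sphere;
    reproducible for a fixed generator state.
    """
    rng = rng or np.random.default_rng()
    dirs = sphere_directions(n_directions, rng)
    counts = [projected_crossings(conformation, d, _rng=rng).count for d in dirs]
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# Alexander fingerprint from a projected diagram
# ---------------------------------------------------------------------------

def _diagram_arcs(curves: Sequence[np.ndarray], cset: CrossingSet):
    """Wirtinger arc structure of a projected diagram.

    Returns (n_arcs, per-crossing (over_arc, under_in, under_out, sign)),
    or None when some component never passes under anything (the diagram
    is then split at this projection: its Alexander evaluations vanish).
    """
    # map global segment index -> (component, position along component)
    sizes = [c.shape[0] for c in curves]
    comp_of_seg = []
    local_of_seg = []
    for ci, n in enumerate(sizes):
        comp_of_seg += [ci] * n
        local_of_seg += list(range(n))

    # events along each component: (position, crossing index, is_under)
    events: list[list[tuple[float, int, bool]]] = [[] for _ in sizes]
    for k, c in enumerate(cset.crossings):
        co, lo = comp_of_seg[c.seg_over], local_of_seg[c.seg_over]
        cu, lu = comp_of_seg[c.seg_under], local_of_seg[c.seg_under]
        events[co].append((lo + c.t_over, k, False))
        events[cu].append((lu + c.t_under, k, True))

    for ci in range(len(sizes)):
        events[ci].sort()

    if any(not any(e[2] for e in ev) for ev in events):
        return None  # a component never goes under: split diagram

    # assign arc ids: arcs are delimited by under events, cyclically
    arc_id = 0
    over_arc = {}
    under_in = {}
    under_out = {}
    for ci, ev in enumerate(events):
        under_positions = [i for i, e in enumerate(ev) if e[2]]
        # arc j runs from under event j to under event j+1 (cyclic)
        base = arc_id
        m = len(under_positions)
        for j, ei in enumerate(under_positions):
            k = ev[ei][1]
            under_out[k] = base + j
            under_in[k] = base + (j - 1) % m
        # over events: find enclosing arc
        for i, e in enumerate(ev):
            if e[2]:
                continue
            k = e[1]
            # arc index: number of under events at position <= this event, -1
            cnt = sum(1 for ei in under_positions if ev[ei][0] < e[0])
            over_arc[k] = base + (cnt - 1) % m
        arc_id += m

    rows = []
    for k, c in enumerate(cset.crossings):
        rows.append((over_arc[k], under_in[k], under_out[k], c.sign))
    return arc_id, rows


def _alexander_eval(n_arcs: int, rows, t: complex) -> complex:
    """|minor determinant| of the Alexander matrix at t (up to units).

    Row for a crossing with over arc o, incoming under arc i, outgoing
    under arc j (Fox calculus of the Wirtinger relation x_j = x_o^e x_i x_o^-e
    with every generator abelianized to t):
        e = +1:  o: 1 - t,  i: t,  j: -1
        e = -1:  o: t - 1,  i: 1,  j: -t   (row multiplied by t)
    """
    n = len(rows)
    if n == 0 or n_arcs != n:
        return 0.0 + 0.0j
    m = np.zeros((n, n), dtype=np.complex128)
    for r, (o, i, j, sign) in enumerate(rows):
        if sign > 0:
            m[r, o] += 1.0 - t
            m[r, i] += t
            m[r, j] += -1.0
        else:
            m[r, o] += t - 1.0
            m[r, i] += 1.0
            m[r, j] += -t
    if n == 1:
        return 0.0 + 0.0j
    sub = m[: n - 1, : n - 1]
    return np.linalg.det(sub)


@dataclass(frozen=True)
class LinkFingerprint:
    """Canonical invariant fingerprint: |Lk| plus Alexander magnitudes.

    The single-variable Alexander evaluations depend on the relative
    orientation of the two components, while the physical rings are
    unoriented; ``alexander`` therefore concatenates the evaluation
    tuples of both relative orientations, sorted into a canonical order,
    so the fingerprint identifies the unoriented link type.
    """
    abs_lk: int
    alexander: tuple[float, ...]

    def matches(self, other: "LinkFingerprint", rtol: float = 1e-4,
                atol: float = 1e-6) -> bool:
        if self.abs_lk != other.abs_lk:
            return False
        return all(math.isclose(a, b, rel_tol=rtol, abs_tol=atol)
                   for a, b in zip(self.alexander, other.alexander))


def writhe_fingerprint(curves) -> int:
    """|Lk| of a two-component system (0 for a single curve)."""
    cs = _curves_of(curves)
    if len(cs) < 2:
        return 0
    return abs(gauss_linking_number(cs[0], cs[1]))


def _diagram_fingerprint_oriented(curves, direction) -> Optional[tuple[float, ...]]:
    cset = projected_crossings(curves, direction)
    arcs = _diagram_arcs(_curves_of(curves), cset)
    if arcs is None:
        return tuple(0.0 for _ in _EVAL_ANGLES)
    n_arcs, rows = arcs
    vals = []
    for ang in _EVAL_ANGLES:
        t = complex(math.cos(ang), math.sin(ang))
        vals.append(abs(_alexander_eval(n_arcs, rows, t)))
    return tuple(vals)


def _diagram_fingerprint(curves, direction) -> Optional[tuple[float, ...]]:
    """Orientation-canonical Alexander evaluations of one projection.

    Both relative orientations of a two-component system are evaluated
    (reversing one component can change the single-variable Alexander
    polynomial); the two tuples are sorted by their rounded values into a
    canonical order and concatenated.
    """
    cs = _curves_of(curves)
    vals_f = _diagram_fingerprint_oriented(cs, direction)
    if len(cs) != 2:
        return vals_f + vals_f
    vals_r = _diagram_fingerprint_oriented([cs[0], cs[1][::-1].copy()],
                                           direction)
    a, b = sorted((tuple(round(v, 4) for v in vals_f),
                   tuple(round(v, 4) for v in vals_r)))
    key_f = tuple(round(v, 4) for v in vals_f)
    if key_f == a:
        return vals_f + vals_r
    return vals_r + vals_f


def alexander_fingerprint(conformation, n_consensus: int = 3,
                          rng: Optional[np.random.Generator] = None,
                          max_attempts: int = 12) -> LinkFingerprint:
    """Invariant fingerprint with consensus over projection directions.

    Evaluates the diagram invariant along ``n_consensus`` generic
    directions; directions keep being drawn until the required number of
    evaluations agree pairwise within tolerance, protecting against
    numerically degenerate diagrams.
    """
    curves = _curves_of(conformation)
    rng = rng or np.random.default_rng(20240321)
    abs_lk = writhe_fingerprint(curves)
    results: list[tuple[float, ...]] = []
    for _ in range(max_attempts):
        d = sphere_directions(1, rng)[0]
        try:
            vals = _diagram_fingerprint(curves, d)
        except DegenerateGeometryError:
            continue
        if vals is None:
            continue
        results.append(vals)
        agreeing = _consensus(results)
        if agreeing is not None and len(agreeing) >= n_consensus:
            arr = np.array(agreeing)
            return LinkFingerprint(abs_lk, tuple(np.median(arr, axis=0)))
    raise DegenerateGeometryError(
        "no consensus among projected diagrams; geometry too degenerate")


def _consensus(results, rtol=1e-3, atol=1e-5):
    """Largest subset of mutually agreeing fingerprint tuples."""
    best = None
    for ref in results:
        group = [r for r in results
                 if all(math.isclose(a, b, rel_tol=rtol, abs_tol=atol)
                        for a, b in zip(ref, r))]
        if best is None or len(group) > len(best):
            best = group
    return best


def identify_link_type(conformation, rng: Optional[np.random.Generator] = None) -> str:
    """Catalog label of a two-component conformation, or ``"unknown"``.

    The fingerprint (|Lk| + Alexander magnitudes) is matched against the
    reference table computed from the catalog's canonical embeddings; the
    shipped topologies are pairwise distinguished by it.  Unresolved
    fingerprints return "unknown", never a wrong catalog label.
    """
    from .catalog import reference_fingerprints  # deferred: avoid cycle
    fp = alexander_fingerprint(conformation, rng=rng)
    for name, ref in reference_fingerprints().items():
        if fp.matches(ref, rtol=1e-3, atol=1e-4):
            return name
    return "unknown"


# ---------------------------------------------------------------------------
# Subchain closure and physical-link localization
# ---------------------------------------------------------------------------

def close_subchain(arc: np.ndarray, system: Optional[np.ndarray] = None,
                   direction: Optional[np.ndarray] = None,
                   scale: float = 6.0) -> np.ndarray:
    """Close an open subchain through a point far outside the system.

    The closure vertex lies at ``scale`` times the system extent from the
    centroid, along ``direction`` if given, otherwise along the outward
    direction through the arc midpoint (minimally interfering closure).
    A closed input (first == last vertex, or no endpoints to join) is
    returned unchanged.
    """
    arc = np.asarray(arc, dtype=np.float64)
    if arc.shape[0] < 2 or np.allclose(arc[0], arc[-1]):
        return arc
    cloud = arc if system is None else np.asarray(system, dtype=np.float64)
    centroid = cloud.mean(axis=0)
    extent = float(np.max(np.linalg.norm(cloud - centroid, axis=1))) or 1.0
    if direction is None:
        mid = arc[arc.shape[0] // 2]
        direction = mid - centroid
        if np.linalg.norm(direction) < 1e-9:
            direction = np.array([0.0, 0.0, 1.0])
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    far = centroid + d * scale * extent
    return np.vstack([arc, far])


@dataclass
class PhysicalLink:
    """Minimal linked subchain pair and its summed contour length."""
    arc1_start: int
    arc1_len: int          # beads
    arc2_start: int
    arc2_len: int
    ell_lk: float          # summed geometric contour length of both arcs
    link_type: str = ""

    def arcs(self, r1: np.ndarray, r2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i1 = (self.arc1_start + np.arange(self.arc1_len)) % r1.shape[0]
        i2 = (self.arc2_start + np.arange(self.arc2_len)) % r2.shape[0]
        return r1[i1], r2[i2]


def _arc_contour_length(arc: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(arc, axis=0), axis=1)))


def _crossing_starts(curves, n_beads, n_dirs=3, margin=4, stride=2,
                     rng=None) -> list[np.ndarray]:
    """Candidate arc start beads: beads near inter-ring crossings, widened
    by ``margin`` and subsampled by ``stride`` (plus all beads as fallback)."""
    rng = rng or np.random.default_rng(7)
    involved = [set(), set()]
    for d in sphere_directions(n_dirs, rng):
        try:
            cs = projected_crossings(curves, d, _rng=rng)
        except DegenerateGeometryError:
            continue
        offset = [0, curves[0].shape[0]]
        for c in cs.crossings:
            if c.is_self:
                continue
            for seg, comp in ((c.seg_over, c.comp_over), (c.seg_under, c.comp_under)):
                local = seg - offset[comp]
                for m in range(-margin, margin + 1):
                    involved[comp].add((local + m) % n_beads[comp])
    out = []
    for ci in range(2):
        beads = sorted(involved[ci])
        if not beads:
            beads = list(range(n_beads[ci]))
        out.append(np.asarray(beads[::stride], dtype=np.int64))
    return out


def locate_physical_link(conformation, min_arc: int = 4,
                         rng: Optional[np.random.Generator] = None,
                         verify: bool = True,
                         coarse: int = 2) -> Optional[PhysicalLink]:
    """Shortest pair of subchains whose closures reproduce the link type.

    Bottom-up search over the summed arc bead count; at each total length,
    candidates are enumerated with ties broken by smaller arc-length
    imbalance and then by lowest starting bead index.  A candidate is
    accepted when the Gauss linking number of the two independently closed
    arcs equals the full conformation's and (``verify``) the closed pair's
    Alexander fingerprint matches the whole link's.  Unlinked input yields
    ``None`` (a no-link result, not an error).
    """
    curves = _curves_of(conformation)
    if len(curves) != 2:
        raise ValueError("physical-link localization needs two rings")
    r1, r2 = curves
    rng = rng or np.random.default_rng(11)
    lk = gauss_linking_number(r1, r2)
    full_fp = alexander_fingerprint(curves, rng=np.random.default_rng(3))
    if full_fp.abs_lk == 0 and all(v < 1e-4 for v in full_fp.alexander):
        return None

    n1, n2 = r1.shape[0], r2.shape[0]
    all_pts = np.vstack(curves)
    centroid = all_pts.mean(axis=0)
    extent = float(np.max(np.linalg.norm(all_pts - centroid, axis=1)))
    # transverse far points on opposite sides keep the two closures apart
    cpt1 = centroid + np.array([0.0, 8.0 * extent, 0.1 * extent])
    cpt2 = centroid + np.array([0.0, -8.0 * extent, -0.1 * extent])

    starts1, starts2 = _crossing_starts(curves, (n1, n2), rng=rng)

    cap = 4096
    out_s1 = np.empty(cap, dtype=np.int64)
    out_l1 = np.empty(cap, dtype=np.int64)
    out_s2 = np.empty(cap, dtype=np.int64)
    out_l2 = np.empty(cap, dtype=np.int64)
    tables = _kernels.precompute_arc_linking(r1, r2, cpt1, cpt2)

    for total in range(2 * min_arc, n1 + n2 + 1, coarse):
        n_cand = _kernels.candidate_scan_fast(
            r1, r2, lk, starts1, starts2, cpt1, cpt2,
            total, min_arc, *tables, out_s1, out_l1, out_s2, out_l2)
        for k in range(min(n_cand, cap)):
            s1, l1 = int(out_s1[k]), int(out_l1[k])
            s2, l2 = int(out_s2[k]), int(out_l2[k])
            a1 = r1[(s1 + np.arange(l1)) % n1]
            a2 = r2[(s2 + np.arange(l2)) % n2]
            if not verify or _closure_consistent(r1, r2, s1, l1, s2, l2,
                                                 all_pts, full_fp):
                ell = _arc_contour_length(a1) + _arc_contour_length(a2)
                return PhysicalLink(s1, l1, s2, l2, ell,
                                    link_type_from(full_fp))
    # fall back: the whole conformation is its own physical link
    ell = _arc_contour_length(np.vstack([r1, r1[:1]])) + \
        _arc_contour_length(np.vstack([r2, r2[:1]]))
    return PhysicalLink(0, n1, 0, n2, ell, link_type_from(full_fp))


def link_type_from(fp: LinkFingerprint) -> str:
    from .catalog import reference_fingerprints
    for name, ref in reference_fingerprints().items():
        if fp.matches(ref, rtol=1e-3, atol=1e-4):
            return name
    return "unknown"


def _closure_consistent(r1, r2, s1, l1, s2, l2, system,
                        full_fp: LinkFingerprint,
                        n_directions: int = 2) -> bool:
    """Closures must reproduce the full fingerprint (consensus over two
    variants of the minimally interfering direction).

    Each arc is closed through a far point on its own side: along the
    axis from the other arc's centroid through its own (the direction
    least likely to sweep through the partner's material); the second
    consensus variant tilts both closures by a common orthogonal
    component.
    """
    n1, n2 = r1.shape[0], r2.shape[0]
    a1 = r1[(s1 + np.arange(l1)) % n1]
    a2 = r2[(s2 + np.arange(l2)) % n2]
    u = a1.mean(axis=0) - a2.mean(axis=0)
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-9 else np.array([0.0, 1.0, 0.0])
    ortho = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(u, [0.0, 1.0, 0.0])
    ortho /= np.linalg.norm(ortho)
    ok = 0
    for tilt in (0.0, 0.45)[:n_directions]:
        c1 = close_subchain(a1, system=system, direction=u + tilt * ortho)
        c2 = close_subchain(a2, system=system, direction=-u + tilt * ortho)
        try:
            # cheap gate: the closed pair's linking number must already
            # agree before the (much costlier) Alexander evaluation
            if abs(gauss_linking_number(c1, c2)) != full_fp.abs_lk:
                return False
            fp = alexander_fingerprint([c1, c2],
                                       rng=np.random.default_rng(5),
                                       n_consensus=2, max_attempts=8)
        except DegenerateGeometryError:
            continue
        if fp.matches(full_fp, rtol=1e-3, atol=1e-4):
            ok += 1
    return ok == n_directions


# ---------------------------------------------------------------------------
# Linear separability
# ---------------------------------------------------------------------------

def is_linearly_separable(points1: np.ndarray, points2: np.ndarray,
                          tol: float = 1e-9) -> bool:
    """True iff a plane strictly separates the two point sets.

    Solved as a linear feasibility program maximizing the margin t of
    w.x + b >= t (set 1) and w.x + b <= -t (set 2) with |w|_inf <= 1;
    the sets are separable iff the optimal margin exceeds ``tol``
    (equivalently, their convex hulls are disjoint).
    """
    p1 = np.asarray(points1, dtype=np.float64)
    p2 = np.asarray(points2, dtype=np.float64)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("point sets must be non-empty")
    # variables: w (3), b, t ; maximize t
    n1, n2 = p1.shape[0], p2.shape[0]
    a_ub = np.zeros((n1 + n2, 5))
    a_ub[:n1, :3] = -p1
    a_ub[:n1, 3] = -1.0
    a_ub[:n1, 4] = 1.0
    a_ub[n1:, :3] = p2
    a_ub[n1:, 3] = 1.0
    a_ub[n1:, 4] = 1.0
    b_ub = np.zeros(n1 + n2)
    c = np.array([0.0, 0.0, 0.0, 0.0, -1.0])
    scale = float(np.abs(np.vstack([p1, p2])).max()) + 1.0
    bounds = [(-1, 1), (-1, 1), (-1, 1), (-2 * scale, 2 * scale), (None, 1.0)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        return False
    return float(res.x[4]) > tol
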