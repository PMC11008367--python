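"""Geometric realization of braid and plat closures as polygonal curves.

Every catalog topology is built from a small combinatorial template: a
word of twist regions applied to parallel "lanes" running along x, closed
either as a braid (return arcs routed around the braid at large y) or as a
plat (end caps pairing adjacent lanes).  Twist regions are half-turn
helices of an adjacent lane pair in the (y, z) plane, so the projection
along z of the ideal embedding reproduces the template's planar diagram
exactly: one crossing per half-turn and no spurious crossings from the
closure arcs.

The builders return one (n_i, 3) polyline per link component, with
vertices spaced finely enough to be resampled to bead chains afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["BraidTemplate", "build_template", "resample_closed",
           "torus_template", "rational_template"]

# geometry constants (in units of the lane spacing before global rescaling)
LANE_GAP = 2.0         # transverse spacing between lanes (y)
TWIST_LEN = 2.6        # x-extent of one half-turn
STRAIGHT_LEN = 1.2     # x-gap between consecutive twist regions
PTS_PER_HALFTURN = 14  # polyline resolution
CAP_PTS = 16


@dataclass(frozen=True)
class BraidTemplate:
    """A braid word on ``n_lanes`` lanes plus a closure convention.

    ``word`` is a sequence of (lane, n_halfturns, sign): the pair
    (lane, lane+1) performs |n_halfturns| half-turns; ``sign`` selects the
    handedness (which strand passes over in the z projection).
    """
    n_lanes: int
    word: tuple[tuple[int, int, int], ...]
    closure: Literal["braid", "plat"]

    @property
    def n_crossings(self) -> int:
        return sum(abs(h) for _, h, _ in self.word)


def torus_template(q: int) -> BraidTemplate:
    """(2, q) torus link: closure of sigma_1^q on two lanes (q even)."""
    if q < 2 or q % 2:
        raise ValueError("2-component torus links need even q >= 2")
    return BraidTemplate(2, ((0, q, 1),), "braid")


def rational_template(partial_quotients: Sequence[int],
                      signs: Sequence[int] | None = None) -> BraidTemplate:
    """4-plat of a rational (2-bridge) link with the given twist counts.

    The twist regions alternate between the middle lane pair (1,2) and the
    bottom pair (0,1); with alternating handedness the canonical
    projection is an alternating diagram, hence minimal (Tait).
    """
    word = []
    if signs is None:
        signs = [1 if i % 2 == 0 else -1 for i in range(len(partial_quotients))]
    for i, (a, s) in enumerate(zip(partial_quotients, signs)):
        lane = 1 if i % 2 == 0 else 0
        word.append((lane, a, s))
    return BraidTemplate(4, tuple(word), "plat")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _lane_paths(template: BraidTemplate) -> tuple[list[np.ndarray], list[int]]:
    """Polyline path of each lane through the braid box and the final
    permutation (path i ends at lane perm[i])."""
    n = template.n_lanes
    # current x position advances region by region
    paths = [[np.array([0.0, LANE_GAP * i, 0.0])] for i in range(n)]
    lane_of_path = list(range(n))  # lane currently occupied by path i
    path_at_lane = list(range(n))
    x = 0.0
    for lane, halfturns, sign in template.word:
        x0 = x + STRAIGHT_LEN
        x1 = x0 + TWIST_LEN * abs(halfturns)
        # advance straight section for all paths
        for i in range(n):
            paths[i].append(np.array([x0, LANE_GAP * lane_of_path[i], 0.0]))
        pa = path_at_lane[lane]
        pb = path_at_lane[lane + 1]
        yc = LANE_GAP * (lane + 0.5)
        r = 0.5 * LANE_GAP
        npts = PTS_PER_HALFTURN * abs(halfturns)
        for k in range(1, npts + 1):
            phi = math.pi * abs(halfturns) * k / npts
            xx = x0 + (x1 - x0) * k / npts
            dy = r * math.cos(phi)
            dz = r * math.sin(phi) * (1 if sign > 0 else -1)
            paths[pa].append(np.array([xx, yc - dy, -dz]))
            paths[pb].append(np.array([xx, yc + dy, dz]))
        # other paths advance straight
        for i in range(n):
            if i != pa and i != pb:
                paths[i].append(np.array([x1, LANE_GAP * lane_of_path[i], 0.0]))
        if halfturns % 2:
            lane_of_path[pa], lane_of_path[pb] = lane_of_path[pb], lane_of_path[pa]
            path_at_lane[lane], path_at_lane[lane + 1] = pb, pa
        x = x1
    x_end = x + STRAIGHT_LEN
    for i in range(n):
        paths[i].append(np.array([x_end, LANE_GAP * lane_of_path[i], 0.0]))
    return [np.array(p) for p in paths], lane_of_path


def _arc(p0: np.ndarray, p1: np.ndarray, bulge: float, axis: int = 1,
         npts: int = CAP_PTS) -> np.ndarray:
    """Semicircular-ish arc from p0 to p1 bulging along coordinate ``axis``."""
    ts = np.linspace(0.0, 1.0, npts + 2)[1:-1]
    base = p0[None, :] * (1 - ts[:, None]) + p1[None, :] * ts[:, None]
    base[:, axis] += bulge * np.sin(math.pi * ts)
    return base


def _dedupe(curve: np.ndarray) -> np.ndarray:
    """Drop consecutive (and wrap-around) duplicate vertices."""
    d = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    keep = np.concatenate([[True], d > 1e-9])
    out = curve[keep]
    if np.linalg.norm(out[0] - out[-1]) <= 1e-9:
        out = out[:-1]
    return out


def build_template(template: BraidTemplate) -> list[np.ndarray]:
    """Closed polyline components of the template's ideal embedding."""
    paths, end_lane = _lane_paths(template)
    n = template.n_lanes
    x_min = 0.0
    x_max = float(paths[0][-1][0])
    y_top = LANE_GAP * (n - 1)

    if template.closure == "braid":
        # path i starts at lane i (left) and ends at lane end_lane[i] (right);
        # the return arc brings lane j's right end back to its left end
        pieces = {i: paths[i] for i in range(n)}
        comps = _trace_components(
            [(i, end_lane[i]) for i in range(n)],
            pieces,
            lambda j: _return_arc(j, n, x_min, x_max, y_top),
        )
        return [_dedupe(c) for c in comps]
    if template.closure == "plat":
        if n % 2:
            raise ValueError("plat closure needs an even number of lanes")
        left_caps = [(2 * i, 2 * i + 1) for i in range(n // 2)]
        right_caps = [(2 * i, 2 * i + 1) for i in range(n // 2)]
        return [_dedupe(c) for c in _trace_plat(paths, end_lane, left_caps,
                                                right_caps, x_min, x_max)]
    raise ValueError(f"unknown closure {template.closure}")


def _return_arc(lane: int, n_lanes: int, x_min: float, x_max: float,
                y_top: float) -> np.ndarray:
    """Return arc of a braid closure: right end of ``lane`` back to its left
    end, routed as a rectangular frame around the braid.  Frames are
    strictly nested (lane 0 outermost in both x and y), so no two return
    arcs cross each other or any lane in the canonical projection."""
    m = n_lanes - 1 - lane
    dx = LANE_GAP * (1.2 + m)
    y_out = y_top + LANE_GAP * (1.2 + m)
    y_lane = LANE_GAP * lane

    def seg(p0, p1, npts=CAP_PTS):
        return np.linspace(p0, p1, npts)[:-1]

    pts = np.vstack([
        seg([x_max, y_lane, 0.0], [x_max + dx, y_lane, 0.0]),
        seg([x_max + dx, y_lane, 0.0], [x_max + dx, y_out, 0.0]),
        seg([x_max + dx, y_out, 0.0], [x_min - dx, y_out, 0.0], 2 * CAP_PTS),
        seg([x_min - dx, y_out, 0.0], [x_min - dx, y_lane, 0.0]),
        seg([x_min - dx, y_lane, 0.0], [x_min, y_lane, 0.0]),
    ])
    return pts[:-1] if np.allclose(pts[-1], [x_min, y_lane, 0.0]) else pts


def _trace_components(end_pairs, pieces, return_arc_fn) -> list[np.ndarray]:
    """Trace closed components of a braid closure."""
    n = len(end_pairs)
    end_lane_of_path = {i: end_pairs[i][1] for i in range(n)}
    path_starting_at = {end_pairs[i][0]: i for i in range(n)}
    seen = set()
    comps = []
    for i0 in range(n):
        if i0 in seen:
            continue
        pts = []
        i = i0
        while True:
            seen.add(i)
            pts.append(pieces[i])
            j = end_lane_of_path[i]
            pts.append(return_arc_fn(j))
            i = path_starting_at[j]
            if i == i0:
                break
        comps.append(np.vstack(pts))
    return comps


def _cap(p0: np.ndarray, p1: np.ndarray, side: int, big: bool = False) -> np.ndarray:
    """End cap joining two lane endpoints; bulges outward along x."""
    bulge = (0.9 if not big else 2.2) * LANE_GAP * side
    return _arc(p0, p1, bulge=bulge, axis=0)


def _trace_plat(paths, end_lane, left_caps, right_caps,
                x_min, x_max) -> list[np.ndarray]:
    """Trace closed components of a plat closure."""
    n = len(paths)
    left_partner = {}
    for a, b in left_caps:
        left_partner[a] = b
        left_partner[b] = a
    right_partner = {}
    for a, b in right_caps:
        right_partner[a] = b
        right_partner[b] = a

    def left_point(lane):
        return np.array([x_min, LANE_GAP * lane, 0.0])

    def right_point(lane):
        return np.array([x_max, LANE_GAP * lane, 0.0])

    def right_cap_arc(a, b):
        return _cap(right_point(a), right_point(b), side=+1)

    seen_left = set()
    comps = []
    # walk: start at a left cap, go through path, right cap, path back, ...
    path_starting_at_lane = {}
    path_ending_at_lane = {}
    for i in range(n):
        path_starting_at_lane[i] = i          # path i starts at lane i (left)
        path_ending_at_lane[end_lane[i]] = i  # and ends at lane end_lane[i]

    for a0 in range(n):
        if a0 in seen_left:
            continue
        pts = []
        lane = a0
        while True:
            seen_left.add(lane)
            i = path_starting_at_lane[lane]
            pts.append(paths[i])
            r = end_lane[i]
            rp = right_partner[r]
            pts.append(right_cap_arc(r, rp))
            i2 = path_ending_at_lane[rp]
            pts.append(paths[i2][::-1])
            l2 = i2  # path i2 starts at left lane i2
            seen_left.add(l2)
            lp = left_partner[l2]
            pts.append(_cap(left_point(l2), left_point(lp), side=-1))
            if lp == a0:
                break
            lane = lp
        comps.append(np.vstack(pts))
    return comps


def resample_closed(curve: np.ndarray, n_beads: int) -> np.ndarray:
    """Resample a closed polyline to ``n_beads`` equally spaced vertices."""
    pts = np.asarray(curve, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    keep = seg > 1e-12
    closed = np.vstack([closed[:-1][keep], closed[-1:]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n_beads, endpoint=False)
    out = np.empty((n_beads, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def eyelet_torus_curves(q: int, rho: float = 0.42) -> list[np.ndarray]:
    """(2, q) torus link decorated with a threaded-tip "eyelet".

    The external tip of the first ring is folded inward and threaded
    through the mutually entangled region: a hairpin runs along the free
    axial core of the twist helix (the axis keeps distance r from both
    winding strands) at z-offsets +-``rho`` and folds just beyond the far
    end of the braid, so that ring's external tip swaps sides.  A folded
    hairpin is retractable along the tube it occupies, so the decorated
    embedding is ambient-isotopic to the plain (2, q) link; only the
    geometry (projected crossing count, threading) changes, while pulling
    the rings apart entrenches the threading instead of undoing it.
    """
    template = torus_template(q)
    paths, end_lane = _lane_paths(template)
    x_min, x_max = 0.0, float(paths[0][-1][0])
    yc = 0.5 * LANE_GAP   # twist-helix axis height
    pads = {0: 4.0, 1: 5.0}
    # slim frames: the decorated state must fit a narrow channel directly,
    # so that tension can entrench the threading before thermal motion in
    # a loose intermediate state retracts it
    y_out = {0: yc + 0.5 * LANE_GAP + 0.8, 1: yc - 0.5 * LANE_GAP - 0.8}
    z_dip = {0: 0.0, 1: -1.6}

    def seg(p0, p1, npts=CAP_PTS):
        return np.linspace(p0, p1, npts)[:-1]

    comps = []
    for lane in (0, 1):
        p = paths[lane]
        lane_y = LANE_GAP * end_lane[lane]
        pad, yo, zd = pads[lane], y_out[lane], z_dip[lane]
        if lane == 0:
            # the hairpin is inserted into the frame's left riser at core
            # height: out along the axis at z=+rho, fold past the right
            # end of the twist region, back at z=-rho, then the riser
            # resumes towards the closure point
            xl = x_min - pad
            comp = np.vstack([
                p,
                seg([x_max, lane_y, 0.0], [x_max + pad, lane_y, zd]),
                seg([x_max + pad, lane_y, zd], [x_max + pad, yo, zd]),
                seg([x_max + pad, yo, zd], [xl, yo, zd], 2 * CAP_PTS),
                seg([xl, yo, zd], [xl, yc + 0.3, 0.0]),
                # hairpin out, fold, and back
                seg([xl, yc + 0.3, 0.0], [xl + 1.0, yc, rho], 8),
                seg([xl + 1.0, yc, rho], [x_max + 1.5, yc, rho], 4 * CAP_PTS),
                seg([x_max + 1.5, yc, rho], [x_max + 2.2, yc, 0.0], 8),
                seg([x_max + 2.2, yc, 0.0], [x_max + 1.5, yc, -rho], 8),
                seg([x_max + 1.5, yc, -rho], [xl + 1.0, yc, -rho],
                    4 * CAP_PTS),
                seg([xl + 1.0, yc, -rho], [xl, yc - 0.3, 0.0], 8),
                # riser resumes
                seg([xl, yc - 0.3, 0.0], [xl, lane_y, 0.0]),
                seg([xl, lane_y, 0.0], [x_min, lane_y, 0.0]),
            ])
        else:
            xl = x_min - pad
            comp = np.vstack([
                p,
                seg([x_max, lane_y, 0.0], [x_max + pad, lane_y, zd]),
                seg([x_max + pad, lane_y, zd], [x_max + pad, yo, zd]),
                seg([x_max + pad, yo, zd], [xl, yo, zd], 2 * CAP_PTS),
                seg([xl, yo, zd], [xl, lane_y, zd]),
                seg([xl, lane_y, zd], [x_min, lane_y, 0.0]),
            ])
        comps.append(_dedupe(comp))
    return comps


def taut_decorated_pair(q: int, arm_a: float, arm_b: float,
                        turns: int | None = None,
                        clasp_radius: float = 1.2,
                        return_radius: float = 2.4,
                        half_width: float | None = None,
                        rho: float = 0.42,
                        decorated: bool = True) -> list[np.ndarray]:
    """Idealized *taut* stretched (2, q) torus link, optionally decorated
    with a threaded-tip eyelet.

    Taut-clasp geometry (lengths in sigma): one strand of each ring winds
    in an antipodal double helix of radius ``clasp_radius`` about the x
    axis over [-w, w] (``turns`` half-turns); the partner strands return
    straight along x at ``return_radius`` on opposite sides (phase 0 for
    ring A, phase pi for ring B).  Ring A's two body strands run in the
    +y half-plane out to -``arm_a``; ring B's in the -y half-plane out to
    +``arm_b``.  With ``decorated`` the external tip of ring A is folded
    inward and threaded through the free core of the winding at
    z-offsets +-``rho``, folding just past its right end: under tension
    the winding presses onto the threaded hairpin and jams it (the
    decoration is ambient-isotopic to the plain link, since a folded
    hairpin retracts along its own tube).
    """
    if q < 2 or q % 2:
        raise ValueError("2-component torus links need even q >= 2")
    if turns is None:
        turns = q
    w = half_width if half_width is not None else max(2.0, 0.6 * turns)
    c = clasp_radius
    co = return_radius
    omega = (turns * math.pi) / (2 * w)

    def helix(phase0, x0, x1):
        npts = max(12, int(12 * abs(x1 - x0)))
        xs = np.linspace(x0, x1, npts)
        ph = phase0 + omega * (xs + w)
        return np.column_stack([xs, c * np.cos(ph), c * np.sin(ph)])

    def line(p0, p1, npts=12):
        return np.linspace(p0, p1, npts)

    # phase at +w (multiple of pi for integer turns)
    end_y = c * math.cos(turns * math.pi)   # +-c, z = 0
    ya1, ya2 = 2.6, 3.8                     # body strand heights

    # --- ring A: body1 -> winding strand -> fold -> return -> body2 -> cap
    cap_x = -arm_a - 1.2
    leg_end = w + 4.5
    pieces = [
        line([-arm_a, ya1, 0.0], [-w - 2.0, ya1, 0.0]),
        line([-w - 2.0, ya1, 0.0], [-w, c, 0.0], 8),
        helix(0.0, -w, w),
        line([w, end_y, 0.0], [w + 0.8, end_y, 0.0], 4),
        line([w + 0.8, end_y, 0.0], [w + 0.8, co, 0.0], 6),   # radial fold
        line([w + 0.8, co, 0.0], [-w, co, 0.0],
             max(12, int(3 * (2 * w)))),                      # return
        line([-w, co, 0.0], [-w - 2.0, ya2, 0.0], 8),
        line([-w - 2.0, ya2, 0.0], [-arm_a, ya2, 0.0]),
    ]
    if decorated:
        # the threaded tip ends in a wide loop (radius ``stopper``) that
        # cannot pass back through the clasp core: a steric stopper that
        # keeps the threading entrenched under tension.  The two half-cap
        # fans take z-separated routes so they never touch each other.
        stopper = 2.4
        loop_x = leg_end + 0.7
        ph = np.linspace(0.5 * math.pi, -0.5 * math.pi, 20)
        tip_loop = np.column_stack([
            np.full(ph.size, loop_x),
            stopper * np.cos(ph),
            stopper * np.sin(ph),
        ])
        zsep = max(0.8, rho + 0.2)
        fold = [line([leg_end, 0.0, rho], [loop_x, 0.0, stopper], 6),
                tip_loop,
                line([loop_x, 0.0, -stopper], [leg_end, 0.0, -rho], 6)]
        pieces += [
            line([-arm_a, ya2, 0.0], [-arm_a - 0.9, 0.55 * ya2, zsep], 8),
            line([-arm_a - 0.9, 0.55 * ya2, zsep], [cap_x, 0.0, rho], 8),
            line([cap_x, 0.0, rho], [leg_end, 0.0, rho],
                 max(16, int(4 * (leg_end - cap_x)))),
            *fold,
            line([leg_end, 0.0, -rho], [cap_x, 0.0, -rho],
                 max(16, int(4 * (leg_end - cap_x)))),
            line([cap_x, 0.0, -rho], [-arm_a - 0.9, 0.55 * ya1, -zsep], 8),
            line([-arm_a - 0.9, 0.55 * ya1, -zsep], [-arm_a, ya1, 0.0], 8),
        ]
    else:
        pieces += [
            _arc(np.array([-arm_a, ya2, 0.0]), np.array([-arm_a, ya1, 0.0]),
                 bulge=-1.2, axis=0),
        ]
    ring_a = _dedupe(np.vstack(pieces))

    # --- ring B: mirrored (bodies at -y, winding phase pi, fold at -w)
    end_yb = -end_y
    pieces_b = [
        line([arm_b, -ya1, 0.0], [w + 2.0, -ya1, 0.0]),
        line([w + 2.0, -ya1, 0.0], [w, end_yb, 0.0], 8),
        helix(math.pi, w, -w),
        line([-w, -c, 0.0], [-w - 0.8, -c, 0.0], 4),
        line([-w - 0.8, -c, 0.0], [-w - 0.8, -co, 0.0], 6),
        line([-w - 0.8, -co, 0.0], [w, -co, 0.0],
             max(12, int(3 * (2 * w)))),
        line([w, -co, 0.0], [w + 2.0, -ya2, 0.0], 8),
        line([w + 2.0, -ya2, 0.0], [arm_b, -ya2, 0.0]),
    ]
    pieces_b += [
        _arc(np.array([arm_b, -ya2, 0.0]), np.array([arm_b, -ya1, 0.0]),
             bulge=1.2, axis=0),
    ]
    ring_b = _dedupe(np.vstack(pieces_b))
    return [ring_a, ring_b]


def taut_deadlock_pair(arm_a: float, arm_b: float, turns: int = 2,
                       clasp_radius: float = 1.3,
                       return_radius: float = 2.3,
                       half_width: float | None = None) -> list[np.ndarray]:
    """Idealized taut *deadlocked* pair: unlinked rings in a double-hooked
    clasp.

    Same taut-clasp construction as :func:`taut_decorated_pair`, but the
    winding strands wind by ``turns`` half-turns over the left half of
    the clasp and unwind over the right half, so the total linking number
    vanishes (the braid word is trivial) while the crossing pattern of
    the wound region resembles a torus clasp.  Pulled taut, the two
    hairpin folds hook each other: the rings are topologically free but
    geometrically deadlocked until thermal motion lets one hook slide
    out.
    """
    w = half_width if half_width is not None else max(2.4, 1.2 * turns)
    c = clasp_radius
    co = return_radius
    omega = (turns * math.pi) / w   # wind over [-w, 0], unwind over [0, w]

    def phase(x):
        x = np.asarray(x)
        return np.where(x <= 0, omega * (x + w), omega * (w - x))

    def helix(phase0, x0, x1):
        npts = max(24, int(12 * abs(x1 - x0)))
        xs = np.linspace(x0, x1, npts)
        ph = phase0 + phase(xs)
        return np.column_stack([xs, c * np.cos(ph), c * np.sin(ph)])

    def line(p0, p1, npts=12):
        return np.linspace(p0, p1, npts)

    ya1, ya2 = 2.0, 3.1   # slim: the taut state fits a D ~ 7 sigma channel
    # both helices start and end at phase offset 0 (total twist zero)
    pieces_a = [
        line([-arm_a, ya1, 0.0], [-w - 2.0, ya1, 0.0]),
        line([-w - 2.0, ya1, 0.0], [-w, c, 0.0], 8),
        helix(0.0, -w, w),
        line([w, c, 0.0], [w + 0.8, c, 0.0], 4),
        line([w + 0.8, c, 0.0], [w + 0.8, co, 0.0], 6),
        line([w + 0.8, co, 0.0], [-w, co, 0.0], max(12, int(3 * 2 * w))),
        line([-w, co, 0.0], [-w - 2.0, ya2, 0.0], 8),
        line([-w - 2.0, ya2, 0.0], [-arm_a, ya2, 0.0]),
        _arc(np.array([-arm_a, ya2, 0.0]), np.array([-arm_a, ya1, 0.0]),
             bulge=-1.2, axis=0),
    ]
    ring_a = _dedupe(np.vstack(pieces_a))
    pieces_b = [
        line([arm_b, -ya1, 0.0], [w + 2.0, -ya1, 0.0]),
        line([w + 2.0, -ya1, 0.0], [w, -c, 0.0], 8),
        helix(math.pi, w, -w),
        line([-w, -c, 0.0], [-w - 0.8, -c, 0.0], 4),
        line([-w - 0.8, -c, 0.0], [-w - 0.8, -co, 0.0], 6),
        line([-w - 0.8, -co, 0.0], [w, -co, 0.0], max(12, int(3 * 2 * w))),
        line([w, -co, 0.0], [w + 2.0, -ya2, 0.0], 8),
        line([w + 2.0, -ya2, 0.0], [arm_b, -ya2, 0.0]),
        _arc(np.array([arm_b, -ya2, 0.0]), np.array([arm_b, -ya1, 0.0]),
             bulge=1.2, axis=0),
    ]
    ring_b = _dedupe(np.vstack(pieces_b))
    return [ring_a, ring_b]
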