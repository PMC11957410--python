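"""Topological defect lines as phase singularities of the wave field.

In three dimensions a complex order parameter (two components: Re S, Im S)
admits line singularities: the permissible defect dimension is
``delta = d - n`` (de Gennes), i.e. ``3 - 2 = 1``.  Along any closed loop
encircling such a line, the phase ``Psi = atan2(Im S, Re S)`` winds by an
integer multiple of ``2 pi``.

Detection discretizes this contour integral: for every pixel of every 2-D
slice of the grid, the cumulative phase difference ``c`` is accumulated
around the counterclockwise loop through its eight neighbors, each step
wrapped to ``(-pi, pi]``.  Pixels with ``round(c / 2 pi) != 0`` are defect
("type 1") pixels.  Slices are scanned along all three axes — a singular
line perpendicular to one slice family is always encircled by loops of at
least one of the other two — and the three masks are unioned.  Type-1
voxels are then coarse-grained into polylines by a depth-first traversal of
their 26-neighbor adjacency graph, split at junctions, and classified as
screw (within 45 degrees of the mean layer normal z) or edge dislocations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import ComplexWaveField

__all__ = [
    "PhaseField",
    "WindingMap",
    "DefectLine",
    "OrderParameterTopology",
    "DefectStatistics",
    "phase_field",
    "winding_map",
    "trace_defect_lines",
    "classify_line",
    "defect_statistics",
    "permissible_defect_dimension",
    "find_defect_lines",
    "track_defects",
]

TWO_PI = 2.0 * math.pi

#: counterclockwise 8-neighbor loop offsets, starting at (-1, -1)
LOOP_OFFSETS = [(-1, -1), (0, -1), (1, -1), (1, 0),
                (1, 1), (0, 1), (-1, 1), (-1, 0)]

#: screw/edge threshold: |cos Phi| >= sqrt(2)/2, i.e. within 45 deg of z
SCREW_COS_THRESHOLD = math.sqrt(2.0) / 2.0


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class PhaseField:
    """Argument field ``Psi(r) = atan2(Im S, Re S)`` in ``(-pi, pi]``."""

    values: np.ndarray
    spacing: float
    periodic: bool = True
    zero_amplitude: np.ndarray | None = None   # voxels where S was exactly 0


@dataclass
class WindingMap:
    """Per-voxel cumulative phase differences and defect labels.

    ``c`` maps scan orientation ('xy', 'yz', 'zx' — the slice plane) to the
    cumulative phase difference array; ``labels`` to the boolean type-1
    masks; ``union`` is the three-orientation union.  Boundary pixels of
    non-periodic fields carry ``c = 0`` and are unlabeled.
    """

    c: dict
    labels: dict
    union: np.ndarray
    spacing: float

    def winding_number(self) -> dict:
        """Nearest-integer winding ``round(c / 2 pi)`` per orientation."""
        return {k: np.rint(v / TWO_PI).astype(int) for k, v in self.c.items()}


@dataclass
class DefectLine:
    """A traced polyline of phase-singular voxels."""

    polyline: np.ndarray        # (m, 3) voxel indices (float for midpoints)
    spacing: float
    winding_sign: int = 0
    closed: bool = False

    @property
    def length(self) -> float:
        if len(self.polyline) < 2:
            return 0.0
        seg = np.diff(self.polyline, axis=0)
        return float(np.sum(np.linalg.norm(seg, axis=1))) * self.spacing

    @property
    def direction(self) -> np.ndarray:
        """Unit end-to-end vector; mean segment direction for closed or
        degenerate lines."""
        v = self.polyline[-1] - self.polyline[0]
        n = np.linalg.norm(v)
        if n < 1e-9 and len(self.polyline) > 2:
            seg = np.diff(self.polyline, axis=0)
            # orient segments consistently before averaging
            ref = seg[np.argmax(np.linalg.norm(seg, axis=1))]
            seg = seg * np.sign(seg @ ref)[:, None]
            v = seg.sum(axis=0)
            n = np.linalg.norm(v)
        if n < 1e-12:
            return np.array([0.0, 0.0, 1.0])
        return v / n

    @property
    def cos_polar(self) -> float:
        """|cos Phi| of the line direction to the layer normal z."""
        return float(abs(self.direction[2]))

    @property
    def mean_polar_angle(self) -> float:
        """Phi in [0, pi/2]: angle between the line and the z axis."""
        return float(math.acos(min(1.0, self.cos_polar)))

    @property
    def kind(self) -> str:
        return classify_line(self)


@dataclass(frozen=True)
class OrderParameterTopology:
    """de Gennes defect-dimension bookkeeping: ``delta = d - n``."""

    d_space: int
    n_components: int

    @property
    def delta_allowed(self) -> int:
        return permissible_defect_dimension(self.d_space, self.n_components)


@dataclass
class DefectStatistics:
    line_density: float         # total length per volume
    count_screw: int
    count_edge: int
    cos_phi_histogram: np.ndarray   # 10 uniform |cos Phi| bins
    total_length: float = 0.0

    @property
    def n_lines(self) -> int:
        return self.count_screw + self.count_edge


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def phase_field(fld: ComplexWaveField) -> PhaseField:
    """Argument of the complex field via the two-argument arctangent.

    Voxels with exactly zero amplitude get phase 0 and are flagged.
    """
    v = fld.values
    zero = (v.real == 0.0) & (v.imag == 0.0)
    psi = np.arctan2(v.imag, v.real)
    # atan2(-0., -1.) = -pi; fold onto (-pi, pi]
    psi[psi == -math.pi] = math.pi
    if zero.any():
        psi[zero] = 0.0
    return PhaseField(values=psi, spacing=fld.spacing, periodic=fld.periodic,
                      zero_amplitude=zero if zero.any() else None)


def wrap_phase(delta: np.ndarray) -> np.ndarray:
    """Map phase differences to ``(-pi, pi]`` (boundary assigned to +pi)."""
    return math.pi - np.mod(math.pi - np.asarray(delta), TWO_PI)


_PLANE_AXES = {"xy": (0, 1), "yz": (1, 2), "zx": (2, 0)}


def _loop_sum(psi: np.ndarray, axes: tuple, periodic: bool) -> np.ndarray:
    """Cumulative wrapped phase difference around the 8-neighbor loop of
    every voxel, with loop steps taken in the two ``axes`` directions."""
    a, b = axes

    def shift(off):
        da, db = off
        return np.roll(np.roll(psi, -da, axis=a), -db, axis=b)

    ring = [shift(off) for off in LOOP_OFFSETS]
    c = np.zeros_like(psi)
    for i in range(8):
        c += wrap_phase(ring[(i + 1) % 8] - ring[i])
    if not periodic:
        # boundary pixels lack a full in-plane 8-neighborhood
        sl = [slice(None)] * psi.ndim
        for ax in (a, b):
            for edge in (0, -1):
                sl_edge = list(sl)
                sl_edge[ax] = edge
                c[tuple(sl_edge)] = 0.0
    return c


def winding_map(psi: PhaseField) -> WindingMap:
    """Eight-neighbor loop winding of the phase, scanned along all three
    axis orientations; union mask of type-1 voxels.

    The wrapped-difference sum around a closed loop telescopes to an exact
    integer multiple of ``2 pi`` (quantization), so labeling by the nearest
    integer of ``c / 2 pi`` is robust.
    """
    if min(psi.values.shape) < 3:
        raise ValueError("grid must be at least 3 voxels per axis")
    c = {}
    labels = {}
    for name, axes in _PLANE_AXES.items():
        cc = _loop_sum(psi.values, axes, psi.periodic)
        c[name] = cc
        labels[name] = np.rint(cc / TWO_PI).astype(int) != 0
    union = labels["xy"] | labels["yz"] | labels["zx"]
    return WindingMap(c=c, labels=labels, union=union, spacing=psi.spacing)


_OFFS26 = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
           for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
# adjacency among the 26 neighbor positions themselves (for the local
# connectivity test of the thinning pass)
_OFF_ADJ = [
    [j for j, q in enumerate(_OFFS26)
     if j != i and max(abs(q[0] - p[0]), abs(q[1] - p[1]),
                       abs(q[2] - p[2])) <= 1]
    for i, p in enumerate(_OFFS26)
]


def _neighbors_connected(present: list) -> bool:
    """Are the given neighbor positions one 26-connected set?"""
    if not present:
        return False
    present_set = set(present)
    stack = [present[0]]
    seen = {present[0]}
    while stack:
        k = stack.pop()
        for j in _OFF_ADJ[k]:
            if j in present_set and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(present)


def _neighbors_clique(present: list) -> bool:
    """Are all present neighbor positions mutually 26-adjacent?  If so the
    voxel is a line tip (all its mass sits on one side) and must be kept."""
    for i, k in enumerate(present):
        adj = _OFF_ADJ[k]
        for j in present[i + 1:]:
            if j not in adj:
                return False
    return True


def _thin_mask(mask: np.ndarray) -> np.ndarray:
    """Sequential connectivity-preserving curve thinning.

    Repeatedly removes voxels whose present 26-neighbors remain a single
    connected set without them (so lines never break) and which are not
    endpoints (fewer than 2 neighbors).  The winding masks are at most a
    couple of voxels thick, so a few sweeps reduce them to one-voxel-wide
    curves.  Out-of-range neighbors are treated as absent.
    """
    m = np.pad(mask, 1, constant_values=False)
    changed = True
    while changed:
        changed = False
        for p in np.argwhere(m):
            x, y, z = p
            present = [k for k, (dx, dy, dz) in enumerate(_OFFS26)
                       if m[x + dx, y + dy, z + dz]]
            if len(present) < 2:
                continue
            if _neighbors_connected(present) and not _neighbors_clique(present):
                m[x, y, z] = False
                changed = True
    return m[1:-1, 1:-1, 1:-1]


def _skeleton_paths(mask: np.ndarray) -> list:
    """Reduce a voxel mask to polyline paths.

    The mask is thinned to a one-voxel-wide skeleton, the skeleton voxels'
    26-neighbor adjacency graph is built, and paths are walked depth-first
    from terminals (degree != 2), splitting at junctions; leftover pure
    cycles are walked from an arbitrary start.
    """
    skel = _thin_mask(mask)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        coords = np.argwhere(mask)
    index = {tuple(c): i for i, c in enumerate(coords)}
    n = len(coords)
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    neighbors = [[] for _ in range(n)]
    for i, c in enumerate(coords):
        for off in offs:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                neighbors[i].append(j)
    degree = np.array([len(nb) for nb in neighbors], dtype=int) \
        if n else np.empty(0, dtype=int)
    used_edges = set()
    visited = np.zeros(n, dtype=bool)
    paths = []

    def walk(start, first):
        """Follow a degree-2 chain from ``start`` via ``first`` until a
        terminal (or the start itself, for cycles)."""
        path = [start, first]
        used_edges.add(frozenset((start, first)))
        visited[start] = visited[first] = True
        prev, cur = start, first
        while degree[cur] == 2:
            nxt = neighbors[cur][0] if neighbors[cur][0] != prev \
                else neighbors[cur][1]
            e = frozenset((cur, nxt))
            if e in used_edges:
                break
            used_edges.add(e)
            visited[nxt] = True
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    terminals = [i for i in range(n) if degree[i] != 2]
    for t in terminals:
        visited[t] = True
        for j in neighbors[t]:
            if frozenset((t, j)) not in used_edges:
                paths.append(walk(t, j))
    # remaining degree-2 voxels form closed cycles
    for i in range(n):
        if not visited[i]:
            if degree[i] == 0:
                visited[i] = True
                paths.append([i])
            else:
                paths.append(walk(i, neighbors[i][0]))
    return [coords[p] for p in paths]


def _dominant_winding_sign(wm: WindingMap, pts: np.ndarray) -> int:
    """Signed winding of a line: the charge of largest magnitude among its
    voxels' per-orientation windings, sign by majority."""
    best = 0
    total = 0
    wnums = wm.winding_number()
    for p in pts:
        idx = tuple(int(v) for v in p)
        w = 0
        for arr in wnums.values():
            if abs(arr[idx]) > abs(w):
                w = int(arr[idx])
        total += w
        if abs(w) > abs(best):
            best = w
    if best == 0:
        return 0
    sign = 1 if total >= 0 else -1
    return sign * abs(best)


def trace_defect_lines(wm: WindingMap, min_length: int = 3) -> list:
    """Coarse-grain the type-1 union mask into defect polylines.

    26-connected components are traversed depth-first; paths split at
    junctions; lines with fewer than ``min_length`` voxels are dropped.
    An empty mask yields an empty list.
    """
    mask = wm.union
    if not mask.any():
        return []
    lines = []
    for pts in _skeleton_paths(mask):
        if len(pts) < min_length:
            continue
        closed = bool(len(pts) > 3 and np.max(np.abs(pts[0] - pts[-1])) <= 1)
        line = DefectLine(polyline=pts.astype(float), spacing=wm.spacing,
                          closed=closed)
        line.winding_sign = _dominant_winding_sign(wm, pts)
        lines.append(line)
    return lines


def classify_line(line: DefectLine) -> str:
    """Screw if within 45 degrees of the layer normal z, else edge."""
    return "screw" if line.cos_polar >= SCREW_COS_THRESHOLD else "edge"


def defect_statistics(lines: list, box_edge: float) -> DefectStatistics:
    """Aggregate line density, screw/edge counts and the |cos Phi|
    histogram (10 uniform bins) for the lines of one field."""
    total = sum(ln.length for ln in lines)
    screw = sum(1 for ln in lines if classify_line(ln) == "screw")
    edge = len(lines) - screw
    cosphis = np.array([ln.cos_polar for ln in lines]) if lines else np.empty(0)
    hist, _ = np.histogram(cosphis, bins=10, range=(0.0, 1.0))
    return DefectStatistics(line_density=total / box_edge ** 3,
                            count_screw=screw, count_edge=edge,
                            cos_phi_histogram=hist, total_length=total)


def permissible_defect_dimension(d_space: int, n_components: int) -> int:
    """de Gennes dimensionality of permissible singularities,
    ``delta = d - n``.

    ``d = 3, n = 2`` (complex order parameter) gives line defects,
    ``delta = 1``.  A negative result means no stable singularity of this
    type exists.
    """
    if d_space < n_components:
        raise ValueError(
            "no stable singularity of this type: "
            f"d - n = {d_space - n_components} < 0")
    return d_space - n_components


def find_defect_lines(fld: ComplexWaveField, min_length: int = 3) -> list:
    """Convenience pipeline: phase -> winding map -> traced lines."""
    return trace_defect_lines(winding_map(phase_field(fld)), min_length)


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

@dataclass
class DefectTrajectory:
    birth_frame: int
    lines: list = dc_field(default_factory=list)   # one DefectLine per frame

    @property
    def death_frame(self) -> int:
        return self.birth_frame + len(self.lines) - 1


def _line_distance(a: DefectLine, b: DefectLine) -> float:
    """Symmetrized mean closest-point distance between two polylines, in
    voxel units."""
    pa, pb = a.polyline, b.polyline
    d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=2)
    return 0.5 * (np.sqrt(d2.min(axis=1)).mean() +
                  np.sqrt(d2.min(axis=0)).mean())


def track_defects(frames: list, min_length: int = 3,
                  match_radius: float = 3.0) -> list:
    """Detect defect lines per frame and link them across consecutive
    frames by minimal mean closest-point distance under ``match_radius``
    (voxel units).  Unmatched lines open or close trajectories.
    """
    if len(frames) < 2:
        raise ValueError("at least two frames are required")
    shapes = {f.values.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("all frames must share one grid")
    per_frame = [find_defect_lines(f, min_length) for f in frames]
    trajectories = []
    active = []          # (trajectory, last line)
    for t, lines in enumerate(per_frame):
        if t == 0:
            for ln in lines:
                tr = DefectTrajectory(birth_frame=0, lines=[ln])
                trajectories.append(tr)
                active.append(tr)
            continue
        pairs = []
        for i, tr in enumerate(active):
            for j, ln in enumerate(lines):
                dist = _line_distance(tr.lines[-1], ln)
                if dist < match_radius:
                    pairs.append((dist, i, j))
        pairs.sort(key=lambda p: p[0])
        used_tr, used_ln = set(), set()
        next_active = []
        for dist, i, j in pairs:
            if i in used_tr or j in used_ln:
                continue
            used_tr.add(i)
            used_ln.add(j)
            active[i].lines.append(lines[j])
            next_active.append(active[i])
        for j, ln in enumerate(lines):
            if j not in used_ln:
                tr = DefectTrajectory(birth_frame=t, lines=[ln])
                trajectories.append(tr)
                next_active.append(tr)
        active = next_active
    return trajectories
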