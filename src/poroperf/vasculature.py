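"""Synthetic vascular trees and their compartment structure.

A :class:`VascularNetwork` is a rooted binary-ish tree of straight cylindrical
segments, stored column-wise in numpy arrays (one row per segment, parent
pointers).  Trees are generated with a staged constrained-constructive-
optimization (CCO) procedure: terminal points are sampled uniformly in the
perfusion domain subject to a distance threshold that shrinks as the tree
fills space, each new terminal is attached to the nearby segment and
bifurcation position that minimize total segment volume, and radii follow
Murray's law r_parent^gamma = sum r_child^gamma under the assumption that
every terminal carries the same outflow.

The hierarchy parameter zeta_j = (total length strictly distal to j) / (total
tree length) places every vessel on a large-to-small scale: ~1 at the inlet,
exactly 0 at terminals.  Compartments are contiguous zeta intervals chosen by
a greedy regression tree that minimizes within-compartment radius variance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "VesselSegment",
    "VascularNetwork",
    "HierarchyLabels",
    "CompartmentScheme",
    "NetworkParseError",
    "generate_cco_tree",
    "hierarchy_parameters",
    "partition_compartments",
    "assign_compartments",
    "apply_blockage",
    "read_segment_table",
    "write_segment_table",
    "write_vtk_polylines",
]

SEGMENT_TABLE_COLUMNS = [
    "id", "parent_id", "x0", "y0", "z0", "x1", "y1", "z1", "radius_mm", "blocked",
]


class NetworkParseError(ValueError):
    """Raised for malformed segment tables (bad rows, orphan/duplicate ids)."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box domain in mm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @classmethod
    def cube(cls, size_mm: float, origin=(0.0, 0.0, 0.0)) -> "Box":
        o = np.asarray(origin, dtype=float)
        return cls(tuple(o), tuple(o + size_mm))

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    @property
    def volume(self) -> float:
        return float(np.prod(self.extent))

    def contains(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lo = np.asarray(self.lo) - tol
        hi = np.asarray(self.hi) + tol
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def on_boundary(self, pt, tol: float = 1e-9) -> bool:
        pt = np.asarray(pt, dtype=float)
        if not self.contains(pt, tol)[0]:
            return False
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return bool(np.any(np.abs(pt - lo) <= tol) or np.any(np.abs(pt - hi) <= tol))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return lo + rng.random((n, 3)) * (hi - lo)


@dataclass(frozen=True)
class VesselSegment:
    """A single cylindrical vessel segment (view into a network row)."""

    id: int
    parent_id: int | None
    proximal: np.ndarray
    distal: np.ndarray
    radius: float
    blocked: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.proximal + self.distal)

    @property
    def direction(self) -> np.ndarray:
        d = self.distal - self.proximal
        return d / np.linalg.norm(d)


class VascularNetwork:
    """Rooted tree of cylindrical vessel segments, array-backed.

    Rows are segments; ``parent[i] == -1`` marks the root.  Connectivity
    invariant: a child's proximal point equals its parent's distal point.
    """

    def __init__(self, proximal, distal, radius, parent, blocked=None, ids=None,
                 validate: bool = True):
        self.proximal = np.ascontiguousarray(proximal, dtype=float).reshape(-1, 3)
        self.distal = np.ascontiguousarray(distal, dtype=float).reshape(-1, 3)
        self.radius = np.ascontiguousarray(radius, dtype=float).ravel()
        self.parent = np.ascontiguousarray(parent, dtype=np.int64).ravel()
        n = len(self.radius)
        self.blocked = (np.zeros(n, dtype=bool) if blocked is None
                        else np.ascontiguousarray(blocked, dtype=bool).ravel())
        self.ids = (np.arange(n, dtype=np.int64) if ids is None
                    else np.ascontiguousarray(ids, dtype=np.int64).ravel())
        if validate:
            self.validate()

    # -- basic derived quantities -------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.radius)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.distal - self.proximal, axis=1)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.proximal + self.distal)

    @property
    def directions(self) -> np.ndarray:
        d = self.distal - self.proximal
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def root_id(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def is_terminal(self) -> np.ndarray:
        term = np.ones(self.n_segments, dtype=bool)
        term[self.parent[self.parent >= 0]] = False
        return term

    @property
    def n_terminals(self) -> int:
        return int(np.count_nonzero(self.is_terminal))

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def children_lists(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_segments)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def depths(self) -> np.ndarray:
        """Root-distance (in segments) of every segment; detects cycles."""
        n = self.n_segments
        depth = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            chain = []
            j = i
            while depth[j] < 0 and self.parent[j] >= 0:
                chain.append(j)
                j = int(self.parent[j])
                if len(chain) > n:
                    raise ValueError("cycle detected in parent pointers")
            if depth[j] < 0:  # j is the root
                depth[j] = 0
            for s in reversed(chain):
                depth[s] = depth[self.parent[s]] + 1
        return depth

    def topological_order(self) -> np.ndarray:
        """Segment indices ordered root-first (parents before children)."""
        return np.argsort(self.depths(), kind="stable")

    def validate(self) -> None:
        n = self.n_segments
        if n == 0:
            raise ValueError("network has no segments")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("all segment lengths must be positive")
        if np.any(self.parent >= n):
            raise ValueError("parent index out of range")
        self.depths()  # raises on cycles
        pos = self.parent >= 0
        gap = np.linalg.norm(self.proximal[pos] - self.distal[self.parent[pos]], axis=1)
        if gap.size and gap.max() > 1e-6:
            raise ValueError("child proximal point must coincide with parent distal point")

    # -- convenience --------------------------------------------------------
    def segment(self, i: int) -> VesselSegment:
        p = self.parent[i]
        return VesselSegment(
            id=int(self.ids[i]),
            parent_id=None if p < 0 else int(self.ids[p]),
            proximal=self.proximal[i].copy(),
            distal=self.distal[i].copy(),
            radius=float(self.radius[i]),
            blocked=bool(self.blocked[i]),
        )

    @property
    def segments(self) -> list[VesselSegment]:
        return [self.segment(i) for i in range(self.n_segments)]

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(self.proximal.copy(), self.distal.copy(),
                               self.radius.copy(), self.parent.copy(),
                               self.blocked.copy(), self.ids.copy(), validate=False)

    def unblocked_terminals(self) -> np.ndarray:
        """Terminals of the perfused subtree: unblocked segments with no
        unblocked children."""
        has_open_child = np.zeros(self.n_segments, dtype=bool)
        pos = (self.parent >= 0) & ~self.blocked
        has_open_child[self.parent[pos]] = True
        return np.flatnonzero(~self.blocked & ~has_open_child)

    def to_dataframe(self) -> pd.DataFrame:
        parent_ids = np.where(self.parent >= 0, self.ids[np.maximum(self.parent, 0)], -1)
        return pd.DataFrame({
            "id": self.ids,
            "parent_id": parent_ids,
            "x0": self.proximal[:, 0], "y0": self.proximal[:, 1], "z0": self.proximal[:, 2],
            "x1": self.distal[:, 0], "y1": self.distal[:, 1], "z1": self.distal[:, 2],
            "radius_mm": self.radius,
            "blocked": self.blocked.astype(int),
        })


# ---------------------------------------------------------------------------
# hierarchy parameter and compartments
# ---------------------------------------------------------------------------

@dataclass
class HierarchyLabels:
    """Per-segment hierarchy parameter zeta in [0, 1)."""

    zeta: np.ndarray
    total_length: float


@dataclass
class CompartmentScheme:
    """Partition of the zeta axis into nc contiguous compartments.

    ``zeta_crit`` is strictly decreasing, first entry 1, last entry 0.
    Segment j belongs to compartment i (1-based) iff
    zeta_j in [zeta_crit[i], zeta_crit[i-1]) using 0-based indexing of the
    vector, with the top interval closed at 1: intervals are closed at their
    lower zeta edge, so a zeta exactly on an interior critical value falls to
    the larger-vessel (lower-index) compartment whose interval it opens.
    """

    nc: int
    zeta_crit: np.ndarray

    def __post_init__(self) -> None:
        zc = np.asarray(self.zeta_crit, dtype=float)
        if len(zc) != self.nc + 1:
            raise ValueError("zeta_crit must have length nc + 1")
        if zc[0] != 1.0 or zc[-1] != 0.0 or np.any(np.diff(zc) >= 0):
            raise ValueError("zeta_crit must be strictly decreasing from 1 to 0")
        self.zeta_crit = zc

    def assign(self, zeta: np.ndarray) -> np.ndarray:
        """Compartment index in 1..nc for each zeta."""
        zeta = np.asarray(zeta, dtype=float)
        if np.any((zeta < 0) | (zeta > 1)):
            raise ValueError("zeta values must lie in [0, 1]")
        asc = self.zeta_crit[::-1]  # ascending: 0 ... 1
        comp = (self.nc + 1) - np.searchsorted(asc, zeta, side="right")
        return np.clip(comp, 1, self.nc).astype(np.int64)


def hierarchy_parameters(network: VascularNetwork) -> HierarchyLabels:
    """zeta_j = (sum of lengths strictly distal to j) / (total length).

    Purely geometric: computed over all segments, blocked or not.  Terminals
    map to exactly 0; the root tends to 1 as the tree grows but never
    reaches it (its own length is excluded from the distal sum).
    """
    lengths = network.lengths
    l_total = float(lengths.sum())
    subtree = lengths.copy()  # length of segment + strict descendants
    order = network.topological_order()
    for i in order[::-1]:  # leaves first
        p = network.parent[i]
        if p >= 0:
            subtree[p] += subtree[i]
    zeta = (subtree - lengths) / l_total
    zeta[network.is_terminal] = 0.0
    return HierarchyLabels(zeta=zeta, total_length=l_total)


def _leaf_sse(cnt, s1, s2):
    # within-leaf sum of squared deviations from aggregated (count, sum, sumsq)
    return s2 - (s1 * s1) / cnt if cnt > 0 else 0.0


def partition_compartments(labels: HierarchyLabels, radii: np.ndarray, nc: int,
                           return_sse: bool = False):
    """Greedy binary regression tree on zeta -> radius, grown to nc leaves.

    At every step the leaf whose best split gives the largest reduction in
    total within-leaf sum of squared radius deviations is split; split
    thresholds are midpoints between adjacent distinct zeta values.  When no
    split reduces the SSE (e.g. constant radii) the largest leaf is split at
    its median zeta.
    """
    zeta = np.asarray(labels.zeta, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if nc < 2:
        raise ValueError("need at least two compartments")
    uz, inv = np.unique(zeta, return_inverse=True)
    if len(uz) < nc:
        raise ValueError(f"nc={nc} exceeds the number of distinct zeta values ({len(uz)})")
    cnt = np.bincount(inv).astype(float)
    s1 = np.bincount(inv, weights=radii)
    s2 = np.bincount(inv, weights=radii * radii)
    c_cnt, c_s1, c_s2 = (np.concatenate([[0.0], np.cumsum(a)]) for a in (cnt, s1, s2))

    def sse(i0, i1):  # over unique-value bins [i0, i1)
        n = c_cnt[i1] - c_cnt[i0]
        if n <= 0:
            return 0.0
        a1 = c_s1[i1] - c_s1[i0]
        a2 = c_s2[i1] - c_s2[i0]
        return max(a2 - a1 * a1 / n, 0.0)

    def best_split(i0, i1):
        """Best interior split k in (i0, i1); returns (reduction, k)."""
        parent = sse(i0, i1)
        best = (-1.0, -1)
        for k in range(i0 + 1, i1):
            red = parent - sse(i0, k) - sse(k, i1)
            if red > best[0] + 1e-15 * max(parent, 1.0):
                best = (red, k)
        return best

    def median_split(i0, i1):
        half = (c_cnt[i0] + c_cnt[i1]) / 2.0
        k = int(np.searchsorted(c_cnt, half, side="left"))
        return min(max(k, i0 + 1), i1 - 1)

    leaves = [(0, len(uz))]
    while len(leaves) < nc:
        cands = [best_split(i0, i1) + (idx,) for idx, (i0, i1) in enumerate(leaves)
                 if i1 - i0 > 1]
        if not cands:
            raise ValueError("no splittable leaf left")
        red_max = max(c[0] for c in cands)
        tol = 1e-12 * max(1.0, sse(0, len(uz)))
        if red_max <= tol:
            # degenerate: zero SSE reduction everywhere -> split the largest
            # leaf at its median zeta (deterministic tie-break)
            splittable = [(i0, i1) for (i0, i1) in leaves if i1 - i0 > 1]
            i0, i1 = max(splittable, key=lambda ab: (c_cnt[ab[1]] - c_cnt[ab[0]], -ab[0]))
            k = median_split(i0, i1)
            leaves.remove((i0, i1))
        else:
            red, k, idx = max(cands, key=lambda c: (c[0], -c[2]))
            i0, i1 = leaves.pop(idx)
        leaves += [(i0, k), (k, i1)]
    cut_bins = sorted({ab[0] for ab in leaves} - {0})
    thresholds = [(uz[k - 1] + uz[k]) / 2.0 for k in cut_bins]  # ascending
    zeta_crit = np.concatenate([[1.0], thresholds[::-1], [0.0]])
    scheme = CompartmentScheme(nc=nc, zeta_crit=zeta_crit)
    if return_sse:
        total = sum(sse(i0, i1) for (i0, i1) in leaves)
        return scheme, total
    return scheme


def assign_compartments(network: VascularNetwork, scheme: CompartmentScheme,
                        labels: HierarchyLabels | None = None) -> np.ndarray:
    """Per-segment compartment index in 1..nc (non-decreasing root->leaf)."""
    if labels is None:
        labels = hierarchy_parameters(network)
    return scheme.assign(labels.zeta)


# ---------------------------------------------------------------------------
# blockage
# ---------------------------------------------------------------------------

def apply_blockage(network: VascularNetwork, segment_id: int) -> VascularNetwork:
    """Mark a segment and its entire distal subtree as blocked.

    Blocked segments carry no flow and are excluded from homogenization.
    Blocking the root is an error (no perfused network would remain).
    """
    idx = np.flatnonzero(network.ids == segment_id)
    if len(idx) == 0:
        raise KeyError(f"segment id {segment_id} not found")
    i0 = int(idx[0])
    if network.parent[i0] < 0:
        raise ValueError("cannot block the root segment")
    out = network.copy()
    mark = np.zeros(out.n_segments, dtype=bool)
    mark[i0] = True
    for i in out.topological_order():
        p = out.parent[i]
        if p >= 0 and mark[p]:
            mark[i] = True
    out.blocked |= mark
    return out


# ---------------------------------------------------------------------------
# CCO generation
# ---------------------------------------------------------------------------

def _point_segment_dist(pt: np.ndarray, prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Distances from a point to each segment (vectorized)."""
    d = dist - prox
    L2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", pt - prox, d) / np.maximum(L2, 1e-30), 0.0, 1.0)
    foot = prox + t[:, None] * d
    return np.linalg.norm(pt - foot, axis=1)


# barycentric grid over the (parent-end, child-end, new-terminal) triangle on
# which candidate bifurcation points are evaluated; corners are excluded to
# avoid zero-length segments
def _bary_grid(m: int = 6) -> np.ndarray:
    w = []
    for a in range(1, m):
        for b in range(1, m - a):
            c = m - a - b
            w.append((a / m, b / m, c / m))
    return np.asarray(w)

_BARY = _bary_grid(6)


def generate_cco_tree(domain: Box, n_terminals: int, inlet_radius: float,
                      inlet_point=None, seed: int = 0, gamma: float = 3.0,
                      n_candidates: int = 8) -> VascularNetwork:
    """Grow a space-filling binary vascular tree inside an axis-aligned box.

    Staged growth: terminal locations are sampled uniformly with a minimum
    distance to the existing tree that shrinks as (V/n)^(1/3); each terminal
    connects to the candidate segment / bifurcation position minimizing the
    total segment volume sum(pi r^2 l) including the upstream radius
    inflation it causes.  Radii are sized by Murray's law with exponent
    ``gamma`` assuming equal outflow at every terminal, which makes
    r_parent^gamma = sum_children r_child^gamma hold exactly and pins the
    root radius at ``inlet_radius``.

    Identical arguments (including seed) reproduce the tree bitwise.
    """
    if n_terminals < 1:
        raise ValueError("n_terminals must be >= 1")
    if inlet_radius <= 0:
        raise ValueError("inlet_radius must be positive")
    if inlet_point is None:
        lo, hi = np.asarray(domain.lo), np.asarray(domain.hi)
        inlet_point = np.array([lo[0], 0.5 * (lo[1] + hi[1]), 0.5 * (lo[2] + hi[2])])
    inlet_point = np.asarray(inlet_point, dtype=float)
    if not domain.on_boundary(inlet_point):
        raise ValueError("inlet_point must lie on the domain boundary")

    rng = np.random.default_rng(seed)
    ex = 2.0 / gamma  # radius^2 ~ n^(2/gamma)

    def sample_point(n_now, prox_a, dist_a):
        d_thresh = 0.8 * (domain.volume / max(n_now, 1)) ** (1.0 / 3.0)
        while True:
            for _ in range(20):
                x = domain.sample(rng)[0]
                if _point_segment_dist(x, prox_a, dist_a).min() > d_thresh:
                    return x
            d_thresh *= 0.85

    # first terminal
    x0 = domain.sample(rng)[0]
    while np.linalg.norm(x0 - inlet_point) < 1e-6:
        x0 = domain.sample(rng)[0]  # pragma: no cover
    prox = [inlet_point]
    dist = [x0]
    parent = [-1]
    ndist = [1]  # terminals fed through each segment

    for t in range(2, n_terminals + 1):
        prox_a = np.asarray(prox)
        dist_a = np.asarray(dist)
        nd = np.asarray(ndist, dtype=float)
        x_new = sample_point(t, prox_a, dist_a)

        dists = _point_segment_dist(x_new, prox_a, dist_a)
        k = min(n_candidates, len(prox))
        cand = np.argpartition(dists, k - 1)[:k]
        cand = cand[np.argsort(dists[cand], kind="stable")]

        best = (np.inf, -1, None)
        for j in cand:
            # upstream volume change from +1 terminal on the path above j
            dv_up = 0.0
            a = parent[j]
            while a >= 0:
                la = np.linalg.norm(dist_a[a] - prox_a[a])
                dv_up += la * ((nd[a] + 1.0) ** ex - nd[a] ** ex)
                a = parent[a]
            # local volumes over candidate bifurcation positions
            tri = np.stack([prox_a[j], dist_a[j], x_new])
            bif = _BARY @ tri
            l_up = np.linalg.norm(bif - prox_a[j], axis=1)
            l_dn = np.linalg.norm(bif - dist_a[j], axis=1)
            l_new = np.linalg.norm(bif - x_new, axis=1)
            ok = (l_up > 1e-9) & (l_dn > 1e-9) & (l_new > 1e-9)
            if not np.any(ok):
                continue
            local = (l_up * (nd[j] + 1.0) ** ex + l_dn * nd[j] ** ex + l_new)
            local[~ok] = np.inf
            q = int(np.argmin(local))
            lj = np.linalg.norm(dist_a[j] - prox_a[j])
            cost = dv_up + local[q] - lj * nd[j] ** ex
            if cost < best[0]:
                best = (cost, int(j), bif[q])
        _, j, bif = best
        if j < 0:  # pragma: no cover - extremely degenerate geometry
            continue
        # split j at bif: new upstream piece adopts j's parent; j keeps its
        # distal part (children untouched); new terminal hangs off the piece
        j_up = len(prox)
        prox.append(prox[j].copy() if isinstance(prox[j], np.ndarray) else np.asarray(prox[j]))
        dist.append(bif.copy())
        parent.append(parent[j])
        ndist.append(ndist[j] + 1)
        prox[j] = bif.copy()
        parent[j] = j_up
        prox.append(bif.copy())
        dist.append(x_new)
        parent.append(j_up)
        ndist.append(1)
        # +1 terminal on the strict ancestors of j_up
        a = parent[j_up]
        while a >= 0:
            ndist[a] += 1
            a = parent[a]

    nd = np.asarray(ndist, dtype=float)
    radius = inlet_radius * (nd / float(n_terminals)) ** (1.0 / gamma)
    return VascularNetwork(np.asarray(prox), np.asarray(dist), radius,
                           np.asarray(parent, dtype=np.int64))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_segment_table(network: VascularNetwork, path) -> None:
    """Write the delimited segment table (header + one row per segment)."""
    df = network.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")


def read_segment_table(path) -> VascularNetwork:
    """Read a segment table; raises :class:`NetworkParseError` on bad input."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise NetworkParseError(f"cannot parse segment table {path}: {exc}") from exc
    missing = [c for c in SEGMENT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkParseError(f"segment table missing columns: {missing}")
    for col in SEGMENT_TABLE_COLUMNS[:-1]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise NetworkParseError(f"malformed value in column {col!r}, row {bad[0]}")
    ids = df["id"].to_numpy(dtype=np.int64)
    if len(np.unique(ids)) != len(ids):
        dup = ids[pd.Series(ids).duplicated().to_numpy()][0]
        raise NetworkParseError(f"duplicate segment id {dup}")
    id_to_row = {int(i): r for r, i in enumerate(ids)}
    parent = np.empty(len(ids), dtype=np.int64)
    for r, pid in enumerate(df["parent_id"].to_numpy(dtype=np.int64)):
        if pid < 0:
            parent[r] = -1
        elif int(pid) in id_to_row:
            parent[r] = id_to_row[int(pid)]
        else:
            raise NetworkParseError(f"row {r}: parent id {pid} not present in table")
    prox = df[["x0", "y0", "z0"]].to_numpy(dtype=float)
    dst = df[["x1", "y1", "z1"]].to_numpy(dtype=float)
    return VascularNetwork(prox, dst, df["radius_mm"].to_numpy(dtype=float),
                           parent, df["blocked"].to_numpy().astype(bool), ids)


def write_vtk_polylines(network: VascularNetwork, path) -> None:
    """Export the tree as legacy-ASCII VTK polylines with radius point data."""
    n = network.n_segments
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nvascular network\nASCII\nDATASET POLYDATA\n")
    buf.write(f"POINTS {2 * n} float\n")
    for i in range(n):
        p, d = network.proximal[i], network.distal[i]
        buf.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n{d[0]:.9g} {d[1]:.9g} {d[2]:.9g}\n")
    buf.write(f"LINES {n} {3 * n}\n")
    for i in range(n):
        buf.write(f"2 {2 * i} {2 * i + 1}\n")
    buf.write(f"POINT_DATA {2 * n}\nSCALARS radius_mm float 1\nLOOKUP_TABLE default\n")
    for i in range(n):
        buf.write(f"{network.radius[i]:.9g}\n{network.radius[i]:.9g}\n")
    Path(path).write_text(buf.getvalue())
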