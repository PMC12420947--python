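"""Tetrahedral meshes: structured cube fixture, geometry, and text VTK I/O.

Only what the P1 solver needs: node coordinates, connectivity, per-element
volumes and shape-function gradients, boundary faces, a 4-point second-order
quadrature rule, and point location for interpolating solutions at vessel
midpoints.  Files are written as legacy-ASCII VTK unstructured grids (plain
text, readable by ParaView); a matching reader ingests files of that form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["TetMesh", "build_cube_mesh", "write_vtk_mesh", "read_vtk_mesh",
           "locate_points", "interpolate_p1"]

# 4-point, degree-2 quadrature on the reference tetrahedron (barycentric)
_QA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_QB = (5.0 - np.sqrt(5.0)) / 20.0
QUAD_BARY = np.array([
    [_QA, _QB, _QB, _QB],
    [_QB, _QA, _QB, _QB],
    [_QB, _QB, _QA, _QB],
    [_QB, _QB, _QB, _QA],
])
QUAD_W = np.full(4, 0.25)  # of the element volume


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with precomputed P1 geometry."""

    nodes: np.ndarray           # (N, 3), mm
    tets: np.ndarray            # (E, 4) int
    volumes: np.ndarray = field(init=False)      # (E,)
    grads: np.ndarray = field(init=False)        # (E, 4, 3)  grad N_a, 1/mm
    h: np.ndarray = field(init=False)            # (E,) max edge length
    boundary_faces: np.ndarray = field(init=False)  # (F, 3) int

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        X = self.nodes[self.tets]                       # (E, 4, 3)
        M = X[:, 1:4] - X[:, 0:1]                       # (E, 3, 3) rows = edges
        detM = np.linalg.det(M)
        if np.any(detM <= 0):
            raise ValueError("all tetrahedra must be positively oriented")
        self.volumes = detM / 6.0
        Minv = np.linalg.inv(M)                         # (E, 3, 3)
        g = np.swapaxes(Minv, 1, 2)                     # rows grad lambda_i
        grads = np.empty((len(self.tets), 4, 3))
        grads[:, 1:4] = g
        grads[:, 0] = -g.sum(axis=1)
        self.grads = grads
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        el = np.stack([np.linalg.norm(X[:, a] - X[:, b], axis=1) for a, b in edges])
        self.h = el.max(axis=0)
        self.boundary_faces = self._extract_boundary()

    def _extract_boundary(self) -> np.ndarray:
        faces = self.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @property
    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def quad_points(self) -> np.ndarray:
        """Physical quadrature points, (E, 4, 3)."""
        return np.einsum("qa,eak->eqk", QUAD_BARY, self.nodes[self.tets])


def build_cube_mesh(n_per_edge: int, size_mm: float = 1.0,
                    origin=(0.0, 0.0, 0.0)) -> TetMesh:
    """Structured cube mesh: n^3 hex cells, 6 tets each (Kuhn subdivision)."""
    n = int(n_per_edge)
    if n < 1:
        raise ValueError("n_per_edge must be >= 1")
    xs = np.linspace(0.0, size_mm, n + 1)
    gi, gj, gk = np.meshgrid(np.arange(n + 1), np.arange(n + 1), np.arange(n + 1),
                             indexing="ij")
    nodes = np.stack([xs[gi], xs[gj], xs[gk]], axis=-1).reshape(-1, 3)
    nodes = nodes + np.asarray(origin, dtype=float)

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    c = {(a, b, d): nid(i + a, j + b, k + d) for a in (0, 1) for b in (0, 1) for d in (0, 1)}
    # six tets around the main diagonal (0,0,0)-(1,1,1)
    paths = [
        ((1, 0, 0), (1, 1, 0)), ((1, 1, 0), (0, 1, 0)), ((0, 1, 0), (0, 1, 1)),
        ((0, 1, 1), (0, 0, 1)), ((0, 0, 1), (1, 0, 1)), ((1, 0, 1), (1, 0, 0)),
    ]
    tets = []
    for a, b in paths:
        tets.append(np.stack([c[(0, 0, 0)], c[a], c[b], c[(1, 1, 1)]], axis=1))
    tets = np.concatenate(tets, axis=0)
    # fix orientation where needed
    X = nodes[tets]
    det = np.linalg.det(X[:, 1:4] - X[:, 0:1])
    flip = det < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    return TetMesh(nodes=nodes, tets=tets)


# ---------------------------------------------------------------------------
# point location / interpolation
# ---------------------------------------------------------------------------

def locate_points(mesh: TetMesh, pts: np.ndarray, tol: float = 1e-9):
    """Find containing element and barycentric coordinates for each point.

    Returns ``(elem, bary)`` with elem = -1 for points outside the mesh.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    X0 = mesh.nodes[mesh.tets[:, 0]]
    M = mesh.nodes[mesh.tets][:, 1:4] - X0[:, None]   # rows are edge vectors
    # x - X0 = M^T lam  =>  lam = M^{-T} (x - X0)
    MinvT = np.swapaxes(np.linalg.inv(M), 1, 2)
    tree = cKDTree(mesh.centroids)
    k = min(48, mesh.n_elements)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    elem = np.full(len(pts), -1, dtype=np.int64)
    bary = np.zeros((len(pts), 4))
    for ip, x in enumerate(pts):
        for e in cand[ip]:
            lam = MinvT[e] @ (x - X0[e])
            b = np.array([1.0 - lam.sum(), lam[0], lam[1], lam[2]])
            if np.all(b >= -tol):
                elem[ip] = e
                bary[ip] = b
                break
        else:
            # exhaustive fallback (rare: warped query far from centroids)
            lam = np.einsum("eij,ej->ei", MinvT, x - X0)
            b4 = np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)
            ok = np.flatnonzero(np.all(b4 >= -tol, axis=1))
            if len(ok):
                elem[ip] = ok[0]
                bary[ip] = b4[ok[0]]
    return elem, bary


def interpolate_p1(mesh: TetMesh, nodal: np.ndarray, elem: np.ndarray,
                   bary: np.ndarray) -> np.ndarray:
    """P1-interpolate a nodal field at located points."""
    vals = np.einsum("pa,pa->p", np.asarray(nodal)[mesh.tets[elem]], bary)
    return vals


# ---------------------------------------------------------------------------
# VTK text I/O
# ---------------------------------------------------------------------------

def write_vtk_mesh(mesh: TetMesh, path, point_data: dict | None = None,
                   cell_data: dict | None = None) -> None:
    """Write a legacy-ASCII VTK unstructured grid with optional data arrays.

    Scalar arrays have shape (N,) / (E,); vector arrays (N, 3); symmetric
    tensors may be passed as (E, 3, 3) and are written as 6-component fields.
    """
    out = ["# vtk DataFile Version 3.0", "poroperf mesh", "ASCII",
           "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    out += [" ".join(f"{v:.17g}" for v in row) for row in mesh.nodes]
    E = mesh.n_elements
    out.append(f"CELLS {E} {5 * E}")
    out += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    out.append(f"CELL_TYPES {E}")
    out += ["10"] * E

    def emit(data: dict, n: int, header: str):
        out.append(f"{header} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.17g}" for v in arr)
            elif arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out.extend(" ".join(f"{v:.17g}" for v in row) for row in arr)
            elif arr.ndim == 3 and arr.shape[1:] == (3, 3):
                comp = arr[:, [0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2]]
                out.append(f"SCALARS {name} double 6")
                out.append("LOOKUP_TABLE default")
                out.extend(" ".join(f"{v:.17g}" for v in row) for row in comp)
            else:
                raise ValueError(f"unsupported data shape for {name}: {arr.shape}")

    if point_data:
        emit(point_data, mesh.n_nodes, "POINT_DATA")
    if cell_data:
        emit(cell_data, E, "CELL_DATA")
    Path(path).write_text("\n".join(out) + "\n")


def read_vtk_mesh(path):
    """Read a legacy-ASCII VTK unstructured tet grid written by this package.

    Returns ``(mesh, point_data, cell_data)`` (scalar/vector arrays only).
    """
    tokens = Path(path).read_text().split("\n")
    i = 0

    def line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        s = tokens[i]
        i += 1
        return s

    for _ in range(4):
        line()  # header, title, ASCII, DATASET
    n_pts = int(line().split()[1])
    nodes = np.array([[float(v) for v in line().split()] for _ in range(n_pts)])
    n_cells = int(line().split()[1])
    tets = np.array([[int(v) for v in line().split()[1:]] for _ in range(n_cells)])
    line()  # CELL_TYPES
    for _ in range(n_cells):
        line()
    point_data: dict = {}
    cell_data: dict = {}
    current = None
    count = 0
    while i < len(tokens):
        try:
            s = line()
        except IndexError:
            break
        if not s.strip():
            continue
        kw = s.split()[0]
        if kw == "POINT_DATA":
            current, count = point_data, int(s.split()[1])
        elif kw == "CELL_DATA":
            current, count = cell_data, int(s.split()[1])
        elif kw == "SCALARS":
            name, ncomp = s.split()[1], int(s.split()[3])
            line()  # LOOKUP_TABLE
            rows = [np.fromstring(line(), sep=" ") for _ in range(count)]
            arr = np.array(rows)
            current[name] = arr.ravel() if ncomp == 1 else arr
        elif kw == "VECTORS":
            name = s.split()[1]
            current[name] = np.array([np.fromstring(line(), sep=" ")
                                      for _ in range(count)])
    return TetMesh(nodes=nodes, tets=tets), point_data, cell_data
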