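"""Ion-pathway (tunnel) detection through a subunit.

A cubic grid anchored at the structure centroid is scored by clearance
(distance to the nearest atom surface). Nodes with clearance above a minimum
probe radius form a 26-connected graph whose edges are weighted by
mean(1/clearance²) x edge length, so the cheapest path hugs wide, central
channel regions (MOLE-style). The path between the nodes nearest the two
seeds is found by Dijkstra, smoothed with a 3-point moving average, and
reported with per-sample clearances; the bottleneck is the minimum clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from poremut.structure import AnalysisConfig, ResidueKey, Structure


@dataclass
class PorePath:
    samples: list[tuple[np.ndarray, float]]
    start_seed: np.ndarray
    end_seed: np.ndarray
    found: bool = True

    @property
    def bottleneck(self) -> float | None:
        if not self.samples:
            return None
        return min(c for _, c in self.samples)

    @property
    def points(self) -> np.ndarray:
        return np.array([p for p, _ in self.samples])


@dataclass
class PoreLining:
    residues: set[ResidueKey]
    cutoff: float


def _clearance_at(points: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                  k: int = 16) -> np.ndarray:
    """Distance from each point to the nearest atom *surface*.

    Nearest-center is not necessarily nearest-surface with mixed radii, so the
    k nearest centers are examined and the minimal surface distance taken.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    k = min(k, len(centers))
    d, idx = tree.query(points, k=k)
    if k == 1:
        d = d[:, None]
        idx = idx[:, None]
    return (d - radii[idx]).min(axis=1)


def find_pore(chain: Structure, start_seed, end_seed,
              config: AnalysisConfig | None = None) -> PorePath:
    """Clearance-weighted cheapest path between two seed points.

    Returns a :class:`PorePath` with ``found=False`` (no samples) when the
    seeds are not connected through open grid nodes ("no tunnel"). A seed
    placed inside an atom is an error.
    """
    config = config or AnalysisConfig()
    start_seed = np.asarray(start_seed, dtype=float)
    end_seed = np.asarray(end_seed, dtype=float)
    atoms = chain.heavy_atoms()
    if not atoms:
        raise ValueError("empty structure")
    centers = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    for name, seed in (("start", start_seed), ("end", end_seed)):
        if np.any(seed < lo - 5.0) or np.any(seed > hi + 5.0):
            raise ValueError(f"{name} seed {seed} outside structure bounding box (+5 Å pad)")
        if _clearance_at(seed[None, :], centers, radii)[0] <= 0.0:
            raise ValueError(f"{name} seed {seed} lies inside an atom")

    # Deterministic grid anchored at the centroid; covers atoms and seeds
    # with a 2-node margin.
    h = config.grid_spacing
    anchor = centers.mean(axis=0)
    glo = np.minimum(lo, np.minimum(start_seed, end_seed)) - 2 * h
    ghi = np.maximum(hi, np.maximum(start_seed, end_seed)) + 2 * h
    i_lo = np.floor((glo - anchor) / h).astype(int)
    i_hi = np.ceil((ghi - anchor) / h).astype(int)
    nx, ny, nz = (i_hi - i_lo + 1)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    nodes = anchor + (np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) + i_lo) * h
    clear = _clearance_at(nodes, centers, radii)
    open_mask = clear > config.probe_min
    if not open_mask.any():
        return PorePath([], start_seed, end_seed, found=False)

    open_idx = np.flatnonzero(open_mask)
    remap = -np.ones(len(nodes), dtype=int)
    remap[open_idx] = np.arange(len(open_idx))
    open_nodes = nodes[open_idx]
    open_clear = clear[open_idx]
    grid_ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])[open_idx]

    # 26-connected edges between open nodes (half the offsets; graph is symmetric)
    offsets = [
        np.array(o)
        for o in [
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
        ]
    ]
    key_of = {tuple(t): n for n, t in enumerate(map(tuple, grid_ijk))}
    rows, cols, wts = [], [], []
    inv2 = 1.0 / open_clear**2
    for off in offsets:
        nb = grid_ijk + off
        length = h * float(np.linalg.norm(off))
        for a, t in enumerate(map(tuple, nb)):
            b = key_of.get(t)
            if b is not None:
                rows.append(a)
                cols.append(b)
                wts.append(0.5 * (inv2[a] + inv2[b]) * length)
    n_open = len(open_nodes)
    graph = coo_matrix((wts, (rows, cols)), shape=(n_open, n_open)).tocsr()

    s = int(np.argmin(np.sum((open_nodes - start_seed) ** 2, axis=1)))
    e = int(np.argmin(np.sum((open_nodes - end_seed) ** 2, axis=1)))
    dist, pred = dijkstra(graph, directed=False, indices=s, return_predecessors=True)
    if not np.isfinite(dist[e]):
        return PorePath([], start_seed, end_seed, found=False)
    path_idx = [e]
    while path_idx[-1] != s:
        path_idx.append(int(pred[path_idx[-1]]))
    path_idx.reverse()
    pts = open_nodes[path_idx]
    if len(pts) >= 3:  # 3-point moving average, endpoints kept
        smooth = pts.copy()
        smooth[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
        pts = smooth
    clearances = _clearance_at(pts, centers, radii)
    samples = [(p, float(c)) for p, c in zip(pts, clearances)]
    return PorePath(samples, start_seed, end_seed, found=True)


def pore_lining_residues(path: PorePath, chain: Structure, cutoff: float = 3.0) -> PoreLining:
    """Residues bordering the pathway.

    A residue is included when any heavy atom lies within
    (local clearance + cutoff) of any path sample.
    """
    if not path.samples:
        return PoreLining(set(), cutoff)
    from scipy.spatial import cKDTree

    atoms = chain.heavy_atoms()
    tree = cKDTree(np.array([a.coord for a in atoms]))
    lining: set[ResidueKey] = set()
    for point, clearance in path.samples:
        for j in tree.query_ball_point(point, clearance + cutoff):
            lining.add(atoms[j].residue_key)
    return PoreLining(lining, cutoff)


def residues_near_points(points, chain: Structure, cutoff: float = 4.5) -> set[ResidueKey]:
    """Residues with any heavy atom within ``cutoff`` of any query point."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return set()
    from scipy.spatial import cKDTree

    atoms = chain.heavy_atoms()
    tree = cKDTree(np.array([a.coord for a in atoms]))
    out: set[ResidueKey] = set()
    for p in points:
        for j in tree.query_ball_point(p, cutoff):
            out.add(atoms[j].residue_key)
    return out


def write_pore_pdb(path: PorePath, file) -> None:
    """Dump the path as HETATM pseudo-atoms (B-factor = clearance) for viewers."""
    lines = []
    for i, (p, c) in enumerate(path.samples, start=1):
        lines.append(
            f"HETATM{i:5d}  O   POR P{i % 10000:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{c:6.2f}           O"
        )
    lines.append("END")
    with open(file, "w") as fh:
        fh.write("\n".join(lines) + "\n")
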