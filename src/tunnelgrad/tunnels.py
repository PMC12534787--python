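"""Tunnel centerline profiles.

Two sources are supported.  Profiles exported by a dedicated tunnel tool
(MOLE-style JSON with per-node coordinates and free radii) are read as-is.
Alternatively a built-in, deliberately simple grid finder computes
widest-bottleneck escape paths from the cofactor to the surface on a
voxelised clearance field.  The finder is not a replacement for a
Voronoi-based tunnel algorithm: its radii are centre-clearance distances to
heavy-atom centres (no van der Waals radii) and it exists so the full
analysis can run self-contained.
"""

from __future__ import annotations

import dataclasses
import heapq
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import FormatError
from .structures import Structure

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProfilePoint:
    coords: np.ndarray  # (3,), Å
    radius: float       # local free radius, Å
    arc_length: float   # cumulative distance along the centerline, Å


@dataclasses.dataclass
class Tunnel:
    tunnel_id: str
    points: list[ProfilePoint]
    # min radius over points; first point is the innermost (cofactor-side) one
    bottleneck: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a tunnel needs at least 2 profile points")
        self.bottleneck = min(p.radius for p in self.points)

    @property
    def length(self) -> float:
        return self.points[-1].arc_length


@dataclasses.dataclass
class TunnelParams:
    """Geometry parameters of the tunnel stage.

    The first five mirror the conventional tunnel-detection settings for
    heme proteins (probe 5 Å, interior threshold 1.1 Å, origin radius 5 Å,
    bottleneck 1.2 Å, surface cover 10 Å); ``grid_spacing`` belongs to the
    built-in finder only.
    """

    probe_radius: float = 5.0
    interior_threshold: float = 1.1
    origin_radius: float = 5.0
    bottleneck_radius: float = 1.2
    surface_cover_radius: float = 10.0
    grid_spacing: float = 0.6

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all tunnel parameters must be positive")
        if self.bottleneck_radius > self.probe_radius:
            raise ValueError("bottleneck_radius must not exceed probe_radius")


def _arc_lengths(coords: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def tunnel_from_nodes(tunnel_id: str, coords: np.ndarray,
                      radii: np.ndarray) -> Tunnel:
    """Assemble a :class:`Tunnel`, recomputing arc length from coordinates."""
    arcs = _arc_lengths(coords)
    pts = [ProfilePoint(np.asarray(c, dtype=float), float(r), float(s))
           for c, r, s in zip(coords, radii, arcs)]
    return Tunnel(tunnel_id, pts)


# ---------------------------------------------------------------------------
# MOLE-style JSON reader

_XYZ_KEYS = (("X", "Y", "Z"), ("x", "y", "z"))
_RADIUS_KEYS = ("FreeRadius", "freeRadius", "Radius", "radius")


def _node_xyz_r(node: dict, tunnel_id: str, i: int) -> tuple[list[float], float]:
    for keys in _XYZ_KEYS:
        if all(k in node for k in keys):
            xyz = [float(node[k]) for k in keys]
            break
    else:
        raise FormatError(
            f"tunnel {tunnel_id} node {i}: no x/y/z coordinates")
    for rk in _RADIUS_KEYS:
        if rk in node:
            r = float(node[rk])
            break
    else:
        raise FormatError(f"tunnel {tunnel_id} node {i}: no free radius")
    if r <= 0:
        raise FormatError(
            f"tunnel {tunnel_id} node {i}: nonpositive radius {r}")
    return xyz, r


def read_mole_tunnels(path: str | Path) -> list[Tunnel]:
    """Read tunnel centerline profiles from a MOLE-style JSON export.

    Accepts either a top-level ``"Tunnels"`` list or one nested under
    ``"Channels"``; each tunnel carries an ordered ``"Profile"`` (or
    ``"Nodes"``) list of nodes with x, y, z and a free radius.  Arc length
    and bottleneck are recomputed, never trusted from the file.  Tunnels
    with fewer than two nodes are skipped with a warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse tunnel JSON {path}: {exc}") from exc

    container = doc
    if isinstance(doc, dict) and "Channels" in doc:
        container = doc["Channels"]
    raw = container.get("Tunnels", []) if isinstance(container, dict) else container
    if not isinstance(raw, list):
        raise FormatError(f"{path}: expected a list of tunnels")

    tunnels: list[Tunnel] = []
    for j, t in enumerate(raw):
        tid = str(t.get("Id", t.get("id", j)))
        nodes = t.get("Profile", t.get("Nodes", t.get("profile")))
        if nodes is None:
            raise FormatError(f"tunnel {tid}: no Profile node list")
        if len(nodes) < 2:
            logger.warning("tunnel %s has %d node(s); skipped", tid, len(nodes))
            continue
        coords, radii = [], []
        for i, node in enumerate(nodes):
            xyz, r = _node_xyz_r(node, tid, i)
            coords.append(xyz)
            radii.append(r)
        tunnels.append(tunnel_from_nodes(tid, np.array(coords), np.array(radii)))
    return tunnels


def export_tunnels_tsv(tunnels: list[Tunnel], path: str | Path) -> None:
    """Write profiles as TSV: tunnel_id, point index, x, y, z, radius, arc."""
    with open(path, "w") as fh:
        fh.write("tunnel_id\tpoint\tx\ty\tz\tradius\tarc_length\n")
        for t in tunnels:
            for i, p in enumerate(t.points):
                fh.write(
                    f"{t.tunnel_id}\t{i}\t{p.coords[0]:.3f}\t{p.coords[1]:.3f}"
                    f"\t{p.coords[2]:.3f}\t{p.radius:.3f}\t{p.arc_length:.3f}\n"
                )


# ---------------------------------------------------------------------------
# built-in grid finder

_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def widest_path_on_field(
    field: np.ndarray,
    passable: np.ndarray,
    start: tuple[int, int, int],
    exit_mask: np.ndarray,
    tie_order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-source widest (max-min) path search on a 3-D scalar field.

    Returns ``(best, parent)`` flat arrays: ``best[v]`` is the maximum over
    paths from ``start`` to voxel ``v`` of the minimum field value along the
    path (-inf if unreachable through ``passable``), and ``parent`` encodes
    predecessor voxels for path backtracking.  ``exit_mask`` only bounds the
    search (it may stop early once all exits are settled); ``tie_order``
    breaks equal-value pops deterministically.
    """
    shape = field.shape
    n = field.size
    flat_field = field.ravel()
    flat_pass = passable.ravel()
    if tie_order is None:
        tie_order = np.arange(n)
    best = np.full(n, -np.inf)
    parent = np.full(n, -1, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    s = int(np.ravel_multi_index(start, shape))
    if not flat_pass[s]:
        return best, parent
    best[s] = flat_field[s]
    heap = [(-best[s], int(tie_order[s]), s)]
    strides = np.array(
        [shape[1] * shape[2], -(shape[1] * shape[2]), shape[2], -shape[2], 1, -1]
    )
    nx, ny, nz = shape
    remaining_exits = int(np.count_nonzero(exit_mask.ravel() & flat_pass))
    while heap:
        negv, _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if exit_mask.ravel()[u]:
            # exits are absorbing: a tunnel ends where it reaches open space,
            # it does not continue through the solvent to other exits
            remaining_exits -= 1
            if remaining_exits == 0:
                break
            continue
        ux, rem = divmod(u, ny * nz)
        uy, uz = divmod(rem, nz)
        for k in range(6):
            dx, dy, dz = _NEIGHBORS[k]
            vx, vy, vz = ux + dx, uy + dy, uz + dz
            if not (0 <= vx < nx and 0 <= vy < ny and 0 <= vz < nz):
                continue
            v = u + int(strides[k])
            if done[v] or not flat_pass[v]:
                continue
            cand = min(-negv, flat_field[v])
            if cand > best[v]:
                best[v] = cand
                parent[v] = u
                heapq.heappush(heap, (-cand, int(tie_order[v]), v))
    return best, parent


def _backtrack(parent: np.ndarray, end: int) -> list[int]:
    path = [end]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    path.reverse()
    return path


def _smooth(coords: np.ndarray, window: int = 3) -> np.ndarray:
    if len(coords) <= 2 or window <= 1:
        return coords
    kernel = np.ones(window) / window
    out = coords.copy()
    inner = np.stack(
        [np.convolve(coords[:, d], kernel, mode="valid") for d in range(3)],
        axis=1,
    )
    out[window // 2: window // 2 + len(inner)] = inner
    return out


def clearance_field(
    coords: np.ndarray, params: TunnelParams, pad: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxelise a padded bounding box and return (distance field, origin, h).

    ``field[i,j,k]`` approximates the distance (Å) from the voxel centre to
    the nearest heavy-atom centre, via an exact Euclidean distance transform
    of the atom-occupancy grid.
    """
    h = params.grid_spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    idx = np.round((coords - lo) / h).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    field = ndimage.distance_transform_edt(~occ, sampling=h)
    return field, lo, h


def find_tunnels(
    structure: Structure,
    params: TunnelParams | None = None,
    seed: int = 0,
    k: int = 5,
) -> list[Tunnel]:
    """Find up to ``k`` widest escape tunnels from the cofactor to the surface.

    Algorithm: voxelise a padded bounding box at ``grid_spacing``; compute
    per-voxel distance to the nearest protein heavy atom; voxels with
    clearance >= ``interior_threshold`` are traversable; voxels near the box
    boundary that are open at probe scale are "outside"; a widest-bottleneck
    (max-min) search runs from the open voxel nearest the cofactor centroid
    (within ``origin_radius``) to outside voxels; paths are smoothed into
    centerlines, tunnels with bottleneck < ``bottleneck_radius`` are
    discarded, and exits closer than ``surface_cover_radius`` to an already
    selected (wider) exit are considered the same tunnel.  Deterministic
    given ``seed`` (the seed only shuffles equal-value tie-breaking).
    """
    if params is None:
        params = TunnelParams()
    if not structure.cofactor_atoms:
        raise ValueError("structure has no cofactor atoms; tunnel origin undefined")
    coords = structure.protein_coords
    pad = params.probe_radius + 2.0
    field, lo, h = clearance_field(coords, params, pad)
    shape = field.shape
    passable = field >= params.interior_threshold

    # the search lives inside the heavy-atom bounding region; a tunnel ends
    # (is absorbed) where it reaches that region's shell or probe-scale open
    # space, so one physical channel cannot fan out into several exits by
    # crawling along the outer surface
    grid_pts = np.indices(shape).reshape(3, -1).T * h + lo
    bbox_lo = coords.min(axis=0) - h
    bbox_hi = coords.max(axis=0) + h
    inside = np.all((grid_pts >= bbox_lo - h) & (grid_pts <= bbox_hi + h),
                    axis=1).reshape(shape)
    shell = inside & ~np.all(
        (grid_pts >= bbox_lo) & (grid_pts <= bbox_hi), axis=1
    ).reshape(shape)
    passable &= inside
    outside = passable & (shell | (field >= params.probe_radius))

    centroid = structure.cofactor_centroid()
    # start: the most open traversable voxel within origin_radius of centroid
    d_centroid = np.linalg.norm(grid_pts - centroid, axis=1).reshape(shape)
    candidates = (d_centroid <= params.origin_radius) & passable & ~outside
    if not candidates.any():
        logger.info("%s: no open voxel near the cofactor; no tunnels",
                    structure.id)
        return []
    cand_field = np.where(candidates, field, -np.inf)
    start = np.unravel_index(int(np.argmax(cand_field)), shape)

    rng = np.random.default_rng(seed)
    tie_order = rng.permutation(field.size)
    best, parent = widest_path_on_field(field, passable, start, outside,
                                        tie_order)

    exits = np.flatnonzero(outside.ravel() & (best > -np.inf))
    if exits.size == 0:
        logger.info("%s: no path from cofactor to surface", structure.id)
        return []
    order = np.lexsort((exits, -best[exits]))  # by value desc, then lex
    chosen: list[int] = []
    chosen_xyz: list[np.ndarray] = []
    for e in exits[order]:
        if best[e] < params.bottleneck_radius:
            break
        exyz = np.array(np.unravel_index(e, shape)) * h + lo
        if any(np.linalg.norm(exyz - c) <= params.surface_cover_radius
               for c in chosen_xyz):
            continue
        chosen.append(int(e))
        chosen_xyz.append(exyz)
        if len(chosen) >= k:
            break

    tunnels: list[Tunnel] = []
    for i, e in enumerate(chosen):
        flat_path = _backtrack(parent, e)
        vox = np.array(np.unravel_index(flat_path, shape)).T
        radii = field[vox[:, 0], vox[:, 1], vox[:, 2]]
        pts = _smooth(vox * h + lo)
        if len(pts) < 2:
            continue
        tunnels.append(tunnel_from_nodes(f"{structure.id}_t{i}", pts, radii))
    return tunnels
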