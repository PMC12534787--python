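"""Self-contained synthetic test cohorts.

The generator builds toy protein structures — idealized Cα-plus-dummy-atom
α-helix bundles arranged as a thick shell around a central cavity — buries a
multi-atom pseudo-cofactor in the cavity, opens one straight channel of
known radius from the cavity to the surface, and emits per-substitution
pathogenicity tables whose per-residue expectation follows a planted
monotone model

    score(residue) = b + g * exp(-d / lambda) + Normal(0, sigma)

with ``d`` the residue's minimum atom distance to the cofactor centroid.
This is exactly the statistical structure the region analysis assumes
(pathogenicity rising toward the cofactor), with known ground truth for
every stage: channel axis and clearance for the tunnel stage, set
membership geometry for the residue-set stage, planted means for the
score stage, and the gradient direction for the statistics.

None of this mimics real protein geometry or real score distributions; the
bundle exists to exercise nearest-atom logic, not physics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .errors import ConstructionError
from .residue_sets import build_region_sets
from .scores import (
    ScoreTable,
    residue_means,
    write_matrix_table,
    write_transcript_table,
    write_variant_table,
)
from .structures import (
    AA1,
    Atom,
    ResidueId,
    Structure,
    residue_centroid_distances,
    write_structure,
)
from .tunnels import Tunnel, tunnel_from_nodes

#: default amino-acid composition (approximate vertebrate globular average)
DEFAULT_COMPOSITION = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å, Cα distance from helix axis


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    The defaults define the reference study conditions used throughout the
    test suite: 30 proteins of 540 residues (a cytochrome-P450-sized chain)
    in an 18-helix five-ring shell, planted gradient amplitude g=0.2
    decaying over lambda=12 Å, residue-level noise sigma=0.05 on a base
    score b=0.3.
    """

    n_proteins: int = 30
    n_residues: int = 540
    n_helices: int = 18
    cofactor_atoms: int = 16
    gradient_amplitude: float = 0.2     # g, score units
    decay_length: float = 12.0          # lambda, Å
    noise_sd: float = 0.05              # sigma, score units
    base_score: float = 0.30            # b
    sub_jitter_sd: float = 0.02         # per-substitution spread, mean-centred
    orientation: str = "pathogenic_high"
    channel_radius: float = 2.0         # Å
    n_channels: int = 1
    cavity_radius: float = 6.0          # Å
    seed: int = 0
    composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gradient_amplitude <= 1.0:
            raise ValueError("gradient_amplitude must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.orientation not in ("pathogenic_high", "pathogenic_low"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def aa_probs(self) -> tuple[list[str], np.ndarray]:
        comp = self.composition or DEFAULT_COMPOSITION
        letters = [a for a in AA1 if comp.get(a, 0) > 0]
        p = np.array([comp[a] for a in letters], dtype=float)
        return letters, p / p.sum()


@dataclasses.dataclass
class ChannelGeometry:
    """Ground truth of a planted channel: axis points from the cavity centre
    to beyond the surface, the construction radius, and the actual clearance
    (min distance from each axis point to any protein atom)."""

    axis_points: np.ndarray  # (M, 3)
    radius: float
    clearances: np.ndarray   # (M,)


def _ray_distance(coords: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Distance from each point to the ray {t * direction : t >= 0}."""
    direction = direction / np.linalg.norm(direction)
    t = coords @ direction
    proj = np.clip(t, 0.0, None)[:, None] * direction[None, :]
    return np.linalg.norm(coords - proj, axis=1)


_CHANNEL_DIRS = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]


def make_structure(
    spec: CohortSpec, index: int
) -> tuple[Structure, list[ChannelGeometry]]:
    """Build one synthetic protein and its planted channel ground truth.

    Deterministic given ``(spec.seed, index)``: the helix geometry depends
    only on ``index``; amino-acid identities are drawn from the composition
    using ``(seed, index)``.
    """
    if spec.cavity_radius < 5.0:
        raise ConstructionError(
            "cavity_radius < 5 Å cannot accommodate the pseudo-cofactor ring")
    n_per_helix = math.ceil(spec.n_residues / spec.n_helices) + 6
    # helices sit in up to five concentric rings, making the shell thick
    # enough that the channel traverses a real distance range
    n_rings = min(5, max(1, spec.n_helices // 3))
    ring_counts = [spec.n_helices // n_rings] * n_rings
    for extra in range(spec.n_helices % n_rings):
        ring_counts[-(extra + 1)] += 1  # extras go to the outer rings
    r_inner = spec.cavity_radius + _HELIX_RADIUS + 0.2
    ring_radii = [r_inner + 4.2 * k for k in range(n_rings)]
    phase = (index * 37) % 360  # per-protein azimuthal offset

    height = n_per_helix * _HELIX_RISE
    # cofactor cavity sits near the bottom of the bundle so that most of the
    # protein body lies far from it (the planted gradient needs a spread of
    # residue-to-cofactor distances)
    z_cavity = -height / 2 + spec.cavity_radius + 2.0
    center = np.array([0.0, 0.0, z_cavity])

    # candidate residues: (helix, k, Cα, CB, CG)
    candidates: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]] = []
    helix_id = 0
    for ring, (ring_n, ring_r) in enumerate(zip(ring_counts, ring_radii)):
        for j in range(ring_n):
            theta = math.radians(phase + 360.0 * j / max(ring_n, 1)
                                 + ring * 180.0 / max(ring_n, 1))
            axis = np.array([ring_r * math.cos(theta),
                             ring_r * math.sin(theta), 0.0])
            u = np.array([math.cos(theta), math.sin(theta), 0.0])
            v = np.array([-math.sin(theta), math.cos(theta), 0.0])
            z0 = -0.5 * (n_per_helix - 1) * _HELIX_RISE
            for k in range(n_per_helix):
                phi = math.radians(_HELIX_TWIST * k + 60.0 * helix_id)
                ca = (axis
                      + _HELIX_RADIUS * (math.cos(phi) * u + math.sin(phi) * v)
                      + np.array([0.0, 0.0, z0 + k * _HELIX_RISE]))
                w = np.array([ca[0], ca[1], 0.0])
                nw = np.linalg.norm(w)
                w = w / nw if nw > 1e-9 else u
                cb = ca + 1.5 * w
                cg = ca + 3.0 * w
                candidates.append((helix_id, k, ca, cb, cg))
            helix_id += 1

    # open the channel(s): drop residues with any atom inside the ray tube
    dirs = _CHANNEL_DIRS[: spec.n_channels]
    kept = []
    for cand in candidates:
        atoms = np.stack(cand[2:]) - center[None, :]
        blocked = any(
            (_ray_distance(atoms, d) < spec.channel_radius).any() for d in dirs
        )
        if not blocked:
            kept.append(cand)
    if len(kept) < spec.n_residues:
        raise ConstructionError(
            f"only {len(kept)} residues fit outside the channel; "
            f"need {spec.n_residues}")
    # trim helix tops (farthest from the cavity first) down to the count
    kept.sort(key=lambda c: (abs(c[2][2] - z_cavity), c[0], c[1]))
    kept = kept[: spec.n_residues]
    kept.sort(key=lambda c: (c[0], c[1]))

    rng = np.random.default_rng([spec.seed % (2**31), index, 0])
    letters, probs = spec.aa_probs()
    aas = rng.choice(letters, size=len(kept), p=probs)

    protein_atoms: list[Atom] = []
    residues: list[ResidueId] = []
    serial = 1
    for i, (h, k, ca, cb, cg) in enumerate(kept):
        rid = ResidueId("A", i + 1, "", str(aas[i]))
        residues.append(rid)
        for name, xyz in (("CA", ca), ("CB", cb), ("CG", cg)):
            protein_atoms.append(Atom(serial, "C", name, xyz, False, rid))
            serial += 1

    # pseudo-cofactor: one central atom plus a flat ring of radius 3 Å
    # (a porphyrin-scale footprint) in the cavity plane
    cof_rid = ResidueId("A", len(kept) + 10, "", "HEM")
    cof_atoms: list[Atom] = []
    n_cof = max(spec.cofactor_atoms, 1)
    cof_atoms.append(Atom(serial, "FE", "FE", center.copy(), True, cof_rid))
    serial += 1
    ring_r_cof = min(3.0, spec.cavity_radius - 2.0)
    for m in range(n_cof - 1):
        ang = 2 * math.pi * m / max(n_cof - 1, 1)
        dz = 1.5 if m % 2 else -1.5  # two staggered rings span the cavity
        xyz = center + np.array([ring_r_cof * math.cos(ang),
                                 ring_r_cof * math.sin(ang), dz])
        cof_atoms.append(Atom(serial, "C", f"C{m+1}", xyz, True, cof_rid))
        serial += 1

    structure = Structure(f"SYN{index:04d}", protein_atoms, cof_atoms, residues)

    channels = []
    coords = structure.protein_coords
    x_max = ring_radii[-1] + _HELIX_RADIUS + 3.5
    for d in dirs:
        ts = np.arange(0.0, x_max, 1.0)
        pts = center[None, :] + ts[:, None] * d[None, :]
        clear = np.array([
            float(np.linalg.norm(coords - p[None, :], axis=1).min())
            for p in pts
        ])
        channels.append(ChannelGeometry(pts, spec.channel_radius, clear))
    return structure, channels


def planted_means(
    spec: CohortSpec, structure: Structure, cofactor_centroid: np.ndarray
) -> np.ndarray:
    """Noise-free planted residue means, aligned with ``structure.residues``
    (always on the pathogenic-high scale)."""
    d = residue_centroid_distances(structure, cofactor_centroid)
    return np.clip(
        spec.base_score
        + spec.gradient_amplitude * np.exp(-d / spec.decay_length),
        0.0, 1.0,
    )


def make_scores(
    spec: CohortSpec,
    structure: Structure,
    cofactor_centroid: np.ndarray,
    index: int | None = None,
    salt: int = 1,
) -> ScoreTable:
    """Planted per-substitution score table for one structure.

    Residue-level noise is Normal(0, sigma); the 19 per-substitution values
    jitter around the residue value with the jitter mean removed, so each
    residue's average equals its (clipped) planted value exactly.  For
    ``pathogenic_low`` orientation every score is emitted as 1 - s.
    """
    if index is None:
        index = int(structure.id.lstrip("SYN") or 0)
    rng = np.random.default_rng([spec.seed % (2**31), index, salt])
    means = planted_means(spec, structure, cofactor_centroid)
    means = np.clip(means + rng.normal(0.0, spec.noise_sd, size=means.size),
                    0.0, 1.0)
    entries: dict[tuple[int, str, str], float] = {}
    for i, rid in enumerate(structure.residues):
        alts = [a for a in AA1 if a != rid.aa]
        jitter = rng.normal(0.0, spec.sub_jitter_sd, size=len(alts))
        jitter -= jitter.mean()
        vals = np.clip(means[i] + jitter, 0.0, 1.0)
        if spec.orientation == "pathogenic_low":
            vals = 1.0 - vals
        for alt, v in zip(alts, vals):
            entries[(rid.number, rid.aa, alt)] = float(v)
    return ScoreTable(structure.id, spec.orientation, entries)


# ---------------------------------------------------------------------------
# planted tunnel profiles

def channel_tunnel(channel: ChannelGeometry, tunnel_id: str = "planted") -> Tunnel:
    """The planted channel as a Tunnel (innermost point first)."""
    return tunnel_from_nodes(tunnel_id, channel.axis_points,
                             channel.clearances)


def make_mole_json(channels: list[ChannelGeometry]) -> dict:
    """MOLE-style JSON document for the planted channels."""
    tunnels = []
    for i, ch in enumerate(channels):
        profile = [
            {"X": float(p[0]), "Y": float(p[1]), "Z": float(p[2]),
             "FreeRadius": float(r)}
            for p, r in zip(ch.axis_points, ch.clearances)
        ]
        tunnels.append({"Id": i + 1, "Profile": profile})
    return {"Channels": {"Tunnels": tunnels}}


def write_mole_json(channels: list[ChannelGeometry], path: str | Path) -> None:
    Path(path).write_text(json.dumps(make_mole_json(channels), indent=1))


# ---------------------------------------------------------------------------
# cohort materialisation

#: (tool name, dialect, orientation) triples emitted per protein
COHORT_TOOLS = (
    ("am_like", "variant", "pathogenic_high"),
    ("sift_like", "matrix", "pathogenic_low"),
    ("pai_like", "transcript", "pathogenic_high"),
)


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Materialise a cohort directory consumable by the pipeline unchanged.

    Layout: per protein a PDB file, a tunnel-profile JSON, and one score
    table per dialect (the matrix dialect on the inverse scale); plus a
    ``manifest.yaml`` run configuration.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": spec.seed, "proteins": [],
                      "tools": [
                          {"name": n, "dialect": d, "orientation": o}
                          for n, d, o in COHORT_TOOLS
                      ]}
    for index in range(spec.n_proteins):
        structure, channels = make_structure(spec, index)
        pdir = out / structure.id
        pdir.mkdir(exist_ok=True)
        write_structure(structure, pdir / "model.pdb")
        write_mole_json(channels, pdir / "tunnels.json")
        centroid = structure.cofactor_centroid()
        entry = {"id": structure.id,
                 "structure": str(pdir / "model.pdb"),
                 "tunnels": str(pdir / "tunnels.json"),
                 "scores": {}}
        for t, (tool, dialect, orientation) in enumerate(COHORT_TOOLS):
            tool_spec = dataclasses.replace(spec, orientation=orientation)
            table = make_scores(tool_spec, structure, centroid,
                                index=index, salt=10 + t)
            path = pdir / f"{tool}.tsv"
            if dialect == "variant":
                write_variant_table(table, path)
            elif dialect == "matrix":
                write_matrix_table(table, path)
            else:
                write_transcript_table(table, path)
            entry["scores"][tool] = str(path)
        manifest["proteins"].append(entry)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out / "manifest.yaml"


# ---------------------------------------------------------------------------
# in-memory cohorts and the vectorised region-mean sampler

def make_cohort_in_memory(spec: CohortSpec, salt: int = 1):
    """Yield (structure, tunnels, score table) per protein without any IO."""
    for index in range(spec.n_proteins):
        structure, channels = make_structure(spec, index)
        tunnels = [channel_tunnel(ch, f"{structure.id}_t{i}")
                   for i, ch in enumerate(channels)]
        table = make_scores(spec, structure, structure.cofactor_centroid(),
                            index=index, salt=salt)
        yield structure, tunnels, table


@dataclasses.dataclass
class CohortGeometry:
    """Score-independent geometry of a cohort, reusable across score draws:
    planted residue means and region-membership index arrays per protein."""

    planted: list[np.ndarray]               # model means per protein
    region_idx: list[dict[str, np.ndarray]]  # residue indices per region


def cohort_geometry(spec: CohortSpec, spacing: float = 0.5,
                    n_atoms: int = 5) -> CohortGeometry:
    planted_list = []
    region_idx = []
    for index in range(spec.n_proteins):
        structure, channels = make_structure(spec, index)
        tunnels = [channel_tunnel(ch) for ch in channels]
        sets = build_region_sets(structure, tunnels, spacing, n_atoms)
        pos = {rid: i for i, rid in enumerate(structure.residues)}
        region_idx.append({
            region: np.array([pos[r] for r in s.members], dtype=int)
            for region, s in sets.items()
        })
        planted_list.append(
            planted_means(spec, structure, structure.cofactor_centroid())
        )
    return CohortGeometry(planted_list, region_idx)


def sample_region_means(
    spec: CohortSpec,
    geometry: CohortGeometry,
    seeds: "list[int] | np.ndarray",
    salt: int = 1,
) -> dict[str, np.ndarray]:
    """Region means for one cohort per entry of ``seeds``, without rebuilding
    structures or per-substitution tables.

    Bitwise-identical to running make_scores -> residue_means ->
    region_summaries on ``dataclasses.replace(spec, seed=s)`` for each seed:
    the residue-level noise stream is the same, and the per-substitution
    jitter is mean-centred so a residue's mean equals its noisy clipped
    value exactly.  Returns, per region, a (len(seeds), n_proteins) array on
    the declared orientation's scale.
    """
    seeds = list(seeds)
    out = {r: np.empty((len(seeds), spec.n_proteins)) for r in
           ("protein", "tunnel", "cofactor")}
    for j in range(spec.n_proteins):
        m = geometry.planted[j]
        for i, s in enumerate(seeds):
            rng = np.random.default_rng([int(s) % (2**31), j, salt])
            noisy = np.clip(m + rng.normal(0.0, spec.noise_sd, size=m.size),
                            0.0, 1.0)
            if spec.orientation == "pathogenic_low":
                noisy = 1.0 - noisy
            for region, idx in geometry.region_idx[j].items():
                out[region][i, j] = noisy[idx].mean()
    return out


# ---------------------------------------------------------------------------
# dense slab fixtures for the tunnel finder

def make_slab_with_channels(
    channel_radii: tuple[float, ...] = (2.0,),
    box: tuple[float, float, float] = (26.0, 26.0, 20.0),
    lattice: float = 1.2,
    cavity_radius: float = 4.0,
) -> tuple[Structure, list[ChannelGeometry]]:
    """A dense atom lattice with a central cavity, a buried pseudo-cofactor
    and straight cylindrical channels of the given radii (first along +z,
    second along +x).  The lattice spacing keeps interstitial clearance
    below the interior threshold, so the walls are tight at finder scale.
    """
    nx, ny, nz = (int(b / lattice) for b in box)
    xs = (np.arange(nx) - (nx - 1) / 2) * lattice
    ys = (np.arange(ny) - (ny - 1) / 2) * lattice
    zs = (np.arange(nz) - (nz - 1) / 2) * lattice
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T

    keep = np.linalg.norm(grid, axis=1) > cavity_radius
    dirs = [np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])]
    for r, d in zip(channel_radii, dirs):
        keep &= _ray_distance(grid, d) > r
    grid = grid[keep]

    rid = ResidueId("A", 1, "", "G")
    atoms = [Atom(i + 1, "C", "CA", xyz, False, rid)
             for i, xyz in enumerate(grid)]
    cof_rid = ResidueId("A", 2, "", "HEM")
    cof = [Atom(len(atoms) + 1, "FE", "FE", np.zeros(3), True, cof_rid)]
    structure = Structure("SLAB", atoms, cof, [rid])

    channels = []
    for r, d in zip(channel_radii, dirs):
        ts = np.arange(0.0, max(box) / 2 + 3.0, 1.0)
        pts = ts[:, None] * d[None, :]
        clear = np.array([
            float(np.linalg.norm(grid - p[None, :], axis=1).min())
            for p in pts
        ])
        channels.append(ChannelGeometry(pts, r, clear))
    return structure, channels
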