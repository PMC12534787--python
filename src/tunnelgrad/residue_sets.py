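"""Geometric residue-set construction.

Three regions are compared throughout the analysis:

* ``protein`` — every residue of the structure;
* ``tunnel``  — residues lining the tunnels: at regular sample points along
  each tunnel centerline, the five closest protein heavy atoms are mapped to
  their parent residues (so each point recruits between one and five
  residues), and the union over points and tunnels forms the set;
* ``cofactor`` — the non-redundant union, over cofactor atoms, of the
  residues owning the five closest protein heavy atoms to each atom.

Distance ties are broken by atom serial so results do not depend on atom
storage order.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .structures import ResidueId, Structure
from .tunnels import Tunnel

logger = logging.getLogger(__name__)

REGIONS = ("protein", "tunnel", "cofactor")


@dataclasses.dataclass
class ResidueSet:
    region: str
    members: list[ResidueId]
    #: per member, the (source label, distance Å) of the closest recruiting
    #: sample point or cofactor atom
    provenance: dict[ResidueId, tuple[str, float]]
    #: number of distinct residues recruited by each source point/atom
    per_source_counts: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("residue-set members must be unique")


def sample_centerline(tunnel: Tunnel, spacing: float) -> np.ndarray:
    """Resample a tunnel centerline at regular arc-length intervals.

    Points sit at arc-length multiples of ``spacing`` from the tunnel start;
    the first and last centerline points are always included.  ``spacing=0``
    returns the native profile nodes unchanged.
    """
    coords = np.array([p.coords for p in tunnel.points], dtype=float)
    arcs = np.array([p.arc_length for p in tunnel.points], dtype=float)
    if spacing < 0:
        raise ValueError("spacing must be >= 0")
    if spacing == 0:
        return coords.copy()
    total = arcs[-1]
    targets = np.arange(0.0, total, spacing)
    if targets.size == 0 or targets[-1] < total:
        targets = np.concatenate([targets, [total]])
    out = np.stack([np.interp(targets, arcs, coords[:, d]) for d in range(3)],
                   axis=1)
    return out


def _nearest_residues(
    structure: Structure, point: np.ndarray, n_atoms: int
) -> list[tuple[ResidueId, float]]:
    """Residues owning the ``n_atoms`` closest protein atoms to ``point``,
    with tie-breaking by (distance, atom serial).  Returns (residue, distance)
    pairs in recruitment order, deduplicated."""
    n_avail = len(structure.protein_atoms)
    k = min(n_atoms, n_avail)
    tree = structure.kdtree()
    # query extra neighbours so that distance ties at the cut are resolved
    # by serial, independent of storage order
    kq = min(k + 5, n_avail)
    dists, idx = tree.query(point, k=kq)
    dists = np.atleast_1d(dists)
    idx = np.atleast_1d(idx)
    serials = structure.protein_serials[idx]
    order = np.lexsort((serials, dists))
    take = order[:k]
    res_idx = structure.atom_residue_index[idx[take]]
    out: list[tuple[ResidueId, float]] = []
    seen: set[ResidueId] = set()
    for ri, d in zip(res_idx, dists[take]):
        rid = structure.residues[ri]
        if rid not in seen:
            seen.add(rid)
            out.append((rid, float(d)))
    return out


def _union_set(
    region: str,
    sources: list[tuple[str, np.ndarray]],
    structure: Structure,
    n_atoms: int,
) -> ResidueSet:
    provenance: dict[ResidueId, tuple[str, float]] = {}
    counts: list[int] = []
    for label, point in sources:
        recruited = _nearest_residues(structure, point, n_atoms)
        counts.append(len(recruited))
        for rid, d in recruited:
            if rid not in provenance or d < provenance[rid][1]:
                provenance[rid] = (label, d)
    author_order = {rid: i for i, rid in enumerate(structure.residues)}
    members = sorted(provenance, key=author_order.__getitem__)
    return ResidueSet(region, members, provenance, counts)


def tunnel_lining_set(
    structure: Structure,
    tunnels: list[Tunnel],
    spacing: float = 0.5,
    n_atoms: int = 5,
) -> ResidueSet:
    """Tunnel-lining residues: union over all tunnels of the residues owning
    the ``n_atoms`` nearest protein atoms at each centerline sample point."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if len(structure.protein_atoms) < n_atoms:
        logger.warning(
            "%s: only %d protein atoms available (< n_atoms=%d)",
            structure.id, len(structure.protein_atoms), n_atoms,
        )
    sources: list[tuple[str, np.ndarray]] = []
    for t in tunnels:
        pts = sample_centerline(t, spacing)
        sources.extend(
            (f"{t.tunnel_id}:p{i}", p) for i, p in enumerate(pts)
        )
    return _union_set("tunnel", sources, structure, n_atoms)


def cofactor_proximal_set(structure: Structure, n_atoms: int = 5) -> ResidueSet:
    """Cofactor-proximal residues: non-redundant union over cofactor atoms of
    the residues owning the ``n_atoms`` nearest protein atoms to each."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not structure.cofactor_atoms:
        raise ValueError("structure has no cofactor atoms")
    sources = [
        (f"cof:{a.serial}", a.coords) for a in structure.cofactor_atoms
    ]
    return _union_set("cofactor", sources, structure, n_atoms)


def protein_set(structure: Structure) -> ResidueSet:
    """The whole-protein region: all residues."""
    return ResidueSet(
        "protein",
        list(structure.residues),
        {r: ("all", 0.0) for r in structure.residues},
        [len(structure.residues)],
    )


def build_region_sets(
    structure: Structure,
    tunnels: list[Tunnel],
    spacing: float = 0.5,
    n_atoms: int = 5,
) -> dict[str, ResidueSet]:
    """Convenience: the three region sets keyed by region name."""
    return {
        "protein": protein_set(structure),
        "tunnel": tunnel_lining_set(structure, tunnels, spacing, n_atoms),
        "cofactor": cofactor_proximal_set(structure, n_atoms),
    }


def export_residue_sets_tsv(
    sets: dict[str, ResidueSet], protein_id: str, path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tregion\tchain\tnumber\taa\tdistance\n")
        for region in REGIONS:
            if region not in sets:
                continue
            s = sets[region]
            for rid in s.members:
                d = s.provenance.get(rid, ("", float("nan")))[1]
                fh.write(
                    f"{protein_id}\t{region}\t{rid.chain}\t{rid.number}"
                    f"\t{rid.aa}\t{d:.3f}\n"
                )
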