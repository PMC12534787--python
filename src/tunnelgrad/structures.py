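"""Reading PDB structures and partitioning atoms into protein and cofactor.

The analysis downstream needs three things from a structure: the heavy atoms
of the polypeptide (with their parent residues), the heavy atoms of a single
cofactor HET group (heme in the motivating system), and the residue
identities in author order.  Everything else in the file — waters, other
ligands, hydrogens, alternate conformations beyond the best one, models past
the first — is deliberately dropped, matching how heavy-atom model
structures (AlphaFold/AlphaFill style) are consumed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, FormatError, MissingCofactorError

#: canonical one/three-letter amino-acid code tables
AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclasses.dataclass(frozen=True)
class ResidueId:
    """Identity of one residue: (chain, author number, insertion code).

    ``aa`` is the one-letter amino-acid code for protein residues and the
    HET code for cofactor groups.
    """

    chain: str
    number: int
    insertion_code: str = ""
    aa: str = "X"

    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain}{self.number}{icode}:{self.aa}"


@dataclasses.dataclass(eq=False)
class Atom:
    serial: int
    element: str
    name: str
    coords: np.ndarray  # shape (3,), Å
    is_het: bool
    parent: ResidueId


class Structure:
    """Heavy atoms of one protein plus one cofactor group.

    Parameters
    ----------
    id:
        Protein identifier (e.g. a UniProt accession or synthetic id).
    protein_atoms, cofactor_atoms:
        Ordered heavy-atom collections; the partition is disjoint.
    residues:
        Protein residues in author order.
    """

    def __init__(
        self,
        id: str,
        protein_atoms: Sequence[Atom],
        cofactor_atoms: Sequence[Atom],
        residues: Sequence[ResidueId],
    ) -> None:
        self.id = id
        self.protein_atoms = list(protein_atoms)
        self.cofactor_atoms = list(cofactor_atoms)
        self.residues = list(residues)
        self.sequence = "".join(r.aa for r in self.residues)
        self._validate()
        self._arrays: dict | None = None
        self._kdtree: cKDTree | None = None

    def _validate(self) -> None:
        serials = [a.serial for a in self.protein_atoms] + [
            a.serial for a in self.cofactor_atoms
        ]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique within the structure")
        known = set(self.residues)
        for a in self.protein_atoms:
            if a.parent not in known:
                raise ValueError(f"atom {a.serial} has unknown parent {a.parent}")

    # -- cached numeric views -------------------------------------------------

    def _build_arrays(self) -> dict:
        coords = np.array([a.coords for a in self.protein_atoms], dtype=float)
        serials = np.array([a.serial for a in self.protein_atoms], dtype=int)
        index_of = {rid: i for i, rid in enumerate(self.residues)}
        res_index = np.array(
            [index_of[a.parent] for a in self.protein_atoms], dtype=int
        )
        return {"coords": coords, "serials": serials, "res_index": res_index}

    @property
    def protein_coords(self) -> np.ndarray:
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays["coords"]

    @property
    def protein_serials(self) -> np.ndarray:
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays["serials"]

    @property
    def atom_residue_index(self) -> np.ndarray:
        """For each protein atom, the index of its parent in ``residues``."""
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays["res_index"]

    @property
    def cofactor_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.cofactor_atoms], dtype=float)

    def cofactor_centroid(self) -> np.ndarray:
        if not self.cofactor_atoms:
            raise MissingCofactorError("<none>")
        return self.cofactor_coords.mean(axis=0)

    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.protein_coords)
        return self._kdtree


def _best_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep, per atom name, the highest-occupancy
    conformer (first-listed on ties)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in atoms:
        if at.name not in best:
            best[at.name] = at
            order.append(at.name)
        elif at.occ > best[at.name].occ:
            best[at.name] = at
    return [best[n] for n in order]


def read_structure(path: str | Path, cofactor_code: str = "HEM") -> Structure:
    """Read a PDB file into a protein/cofactor partitioned :class:`Structure`.

    Hydrogens are excluded everywhere; waters and HET groups other than
    ``cofactor_code`` are ignored; only the first model is read; alternate
    locations resolve to the highest-occupancy conformer.

    Raises
    ------
    FormatError
        if the file cannot be parsed as PDB.
    MissingCofactorError
        if no residue carries ``cofactor_code``.
    EmptyStructureError
        if the file contains no standard amino-acid residues.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    model = st[0]

    protein_atoms: list[Atom] = []
    cofactor_atoms: list[Atom] = []
    residues: list[ResidueId] = []
    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            heavy = [
                a for a in _best_altloc(res) if not a.element.is_hydrogen
            ]
            if name == cofactor_code.upper():
                rid = ResidueId(chain.name, res.seqid.num,
                                (res.seqid.icode or " ").strip(), name)
                for a in heavy:
                    cofactor_atoms.append(
                        Atom(a.serial, a.element.name, a.name,
                             np.array([a.pos.x, a.pos.y, a.pos.z]), True, rid)
                    )
            elif name in AA3_TO_1:
                rid = ResidueId(chain.name, res.seqid.num,
                                (res.seqid.icode or " ").strip(),
                                AA3_TO_1[name])
                residues.append(rid)
                for a in heavy:
                    protein_atoms.append(
                        Atom(a.serial, a.element.name, a.name,
                             np.array([a.pos.x, a.pos.y, a.pos.z]), False, rid)
                    )
            # waters and other HET groups: ignored entirely
            elif name in _WATER_NAMES:
                continue

    if not residues:
        raise EmptyStructureError(f"no protein residues in {path}")
    if not cofactor_atoms:
        raise MissingCofactorError(cofactor_code, str(path))
    return Structure(path.stem, protein_atoms, cofactor_atoms, residues)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` back to PDB (protein as ATOM, cofactor as
    HETATM).  Used mainly by the synthetic generator."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def _chain(name: str) -> gemmi.Chain:
        if name not in chains:
            chains[name] = gemmi.Chain(name)
        return chains[name]

    def _emit(atoms: list[Atom], het: bool) -> None:
        # gemmi containers copy on add, so residues are filled before adding
        groups: list[tuple[tuple, list[Atom]]] = []
        for a in atoms:
            key = (a.parent.chain, a.parent.number, a.parent.insertion_code,
                   a.parent.aa)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        for (chain_name, number, icode, aa), group in groups:
            res = gemmi.Residue()
            res.name = aa if het else AA1_TO_3[aa]
            res.seqid = gemmi.SeqId(number, icode or " ")
            res.het_flag = "H" if het else "A"
            for a in group:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.serial = a.serial
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                res.add_atom(ga)
            _chain(chain_name).add_residue(res)

    _emit(structure.protein_atoms, het=False)
    _emit(structure.cofactor_atoms, het=True)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def residue_centroid_distances(
    structure: Structure, point: np.ndarray
) -> np.ndarray:
    """Per-residue minimum atom distance (Å) to ``point``.

    Returns an array aligned with ``structure.residues``.
    """
    point = np.asarray(point, dtype=float)
    d = np.linalg.norm(structure.protein_coords - point[None, :], axis=1)
    out = np.full(len(structure.residues), np.inf)
    np.minimum.at(out, structure.atom_residue_index, d)
    return out
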