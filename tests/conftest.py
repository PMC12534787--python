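"""Shared fixtures: a hand-written toy PDB exercising parser edge cases and
small synthetic cohort specs."""

from __future__ import annotations

import numpy as np
import pytest

from tunnelgrad.synthetic import CohortSpec


def pdb_line(record: str, serial: int, name: str, alt: str, resname: str,
             chain: str, resseq: int, x: float, y: float, z: float,
             occ: float, element: str) -> str:
    return (
        f"{record:<6}{serial:>5} {name:<4}{alt:1}{resname:<3} {chain:1}"
        f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """ALA-GLY-PHE plus a 4-atom pseudo-HEM, with a hydrogen, a water, an
    unrelated HET group, and an altloc pair (B has higher occupancy)."""
    lines = [
        pdb_line("ATOM", 1, " N", " ", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0, "N"),
        pdb_line("ATOM", 2, " CA", "A", "ALA", "A", 1, 1.0, 0.0, 0.0, 0.4, "C"),
        pdb_line("ATOM", 3, " CA", "B", "ALA", "A", 1, 1.5, 0.0, 0.0, 0.6, "C"),
        pdb_line("ATOM", 4, " HA", " ", "ALA", "A", 1, 1.0, 1.0, 0.0, 1.0, "H"),
        pdb_line("ATOM", 5, " N", " ", "GLY", "A", 2, 3.0, 0.0, 0.0, 1.0, "N"),
        pdb_line("ATOM", 6, " CA", " ", "GLY", "A", 2, 4.0, 0.0, 0.0, 1.0, "C"),
        pdb_line("ATOM", 7, " N", " ", "PHE", "A", 3, 6.0, 0.0, 0.0, 1.0, "N"),
        pdb_line("ATOM", 8, " CA", " ", "PHE", "A", 3, 7.0, 0.0, 0.0, 1.0, "C"),
        pdb_line("HETATM", 9, "FE", " ", "HEM", "A", 90, 2.0, 3.0, 0.0, 1.0, "FE"),
        pdb_line("HETATM", 10, " C1", " ", "HEM", "A", 90, 3.0, 3.0, 0.0, 1.0, "C"),
        pdb_line("HETATM", 11, " C2", " ", "HEM", "A", 90, 2.0, 4.0, 0.0, 1.0, "C"),
        pdb_line("HETATM", 12, " C3", " ", "HEM", "A", 90, 1.0, 3.0, 0.0, 1.0, "C"),
        pdb_line("HETATM", 13, " O", " ", "HOH", "A", 91, 9.0, 9.0, 0.0, 1.0, "O"),
        pdb_line("HETATM", 14, " C1", " ", "NAG", "A", 92, 9.0, 0.0, 3.0, 1.0, "C"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_spec():
    """A light cohort spec for unit tests (the module-default study spec is
    exercised in the acceptance tests)."""
    return CohortSpec(n_proteins=3, n_residues=120, n_helices=6,
                      cofactor_atoms=8, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
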