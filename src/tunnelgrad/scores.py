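"""Per-substitution pathogenicity tables and per-residue aggregation.

Three table dialects are read into one common :class:`ScoreTable`:

* long-form variant tables (protein id, variant string like ``A123V``,
  score) — the AlphaMissense-style export;
* position x substitution matrices (one row per position, one column per
  substitute amino acid) — the SIFT-style export, conventionally on an
  inverse scale where LOW means pathogenic;
* transcript-variant tables (transcript id, variant, score) — the
  PrimateAI-3D-style export.

Scale orientation (``pathogenic_high`` vs ``pathogenic_low``) is carried as
metadata and never applied to the numbers here; only the direction logic of
the region statistics consumes it.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .structures import AA1, ResidueId, Structure

logger = logging.getLogger(__name__)

ORIENTATIONS = ("pathogenic_high", "pathogenic_low")
_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclasses.dataclass
class ScoreTable:
    protein_id: str
    orientation: str
    #: (position 1-based, ref one-letter, alt one-letter) -> score in [0, 1]
    entries: dict[tuple[int, str, str], float]

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for (pos, ref, alt), s in self.entries.items():
            if ref == alt:
                raise ValueError(f"synonymous entry {ref}{pos}{alt}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1] at {ref}{pos}{alt}")

    def positions(self) -> set[int]:
        return {pos for pos, _, _ in self.entries}

    def entries_at(self, position: int) -> dict[tuple[str, str], float]:
        return {
            (ref, alt): s
            for (pos, ref, alt), s in self.entries.items()
            if pos == position
        }

    def inverted(self) -> "ScoreTable":
        """s -> 1 - s with the declared orientation flipped."""
        flipped = ORIENTATIONS[1 - ORIENTATIONS.index(self.orientation)]
        return ScoreTable(
            self.protein_id,
            flipped,
            {k: 1.0 - v for k, v in self.entries.items()},
        )


@dataclasses.dataclass
class ResidueScore:
    residue: ResidueId
    mean_score: float | None  # None marks a residue with no available entries
    n_substitutions: int


@dataclasses.dataclass
class ResidueMeans:
    """Per-residue mean pathogenicity plus a reference-mismatch report."""

    protein_id: str
    orientation: str
    scores: dict[ResidueId, ResidueScore]
    #: (position, table ref aa, structure aa) where the two disagree
    mismatches: list[tuple[int, str, str]]

    def available(self) -> dict[ResidueId, float]:
        return {
            r: s.mean_score
            for r, s in self.scores.items()
            if s.mean_score is not None
        }


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_variant(text: str, line: int) -> tuple[str, int, str]:
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise FormatError(f"line {line}: variant {text!r} is not of the form "
                          "<ref><position><alt>")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def _read_long_form(
    path: Path, orientation: str, id_col_candidates: tuple[str, ...]
) -> ScoreTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[c] for c in id_col_candidates if c in cols), None)
    var_col = next((cols[c] for c in ("variant", "mutation", "substitution")
                    if c in cols), None)
    score_col = next((cols[c] for c in ("score", "pathogenicity", "value")
                      if c in cols), None)
    if not (id_col and var_col and score_col):
        raise FormatError(
            f"{path}: need id/variant/score columns, found {list(df.columns)}")
    id_i = df.columns.get_loc(id_col)
    var_i = df.columns.get_loc(var_col)
    score_i = df.columns.get_loc(score_col)
    protein_id = None
    entries: dict[tuple[int, str, str], float] = {}
    for i, row in enumerate(df.itertuples(index=False, name=None), start=2):
        protein_id = protein_id or str(row[id_i])
        variant = str(row[var_i])
        ref, pos, alt = _parse_variant(variant, i)
        if ref == alt:
            logger.warning("%s line %d: synonymous variant %s skipped",
                           path.name, i, variant)
            continue
        raw = row[score_i]
        try:
            score = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} line {i}: bad score {raw!r}") from exc
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{path} line {i}: score {score} outside [0, 1]")
        key = (pos, ref, alt)
        if key in entries:
            logger.warning("%s line %d: duplicate entry %s; last value wins",
                           path.name, i, variant)
        entries[key] = score
    return ScoreTable(protein_id or path.stem, orientation, entries)


def read_variant_table(
    path: str | Path, orientation: str = "pathogenic_high"
) -> ScoreTable:
    """Read a long-form variant table (protein id, variant, score)."""
    return _read_long_form(Path(path), orientation,
                           ("protein_id", "uniprot", "protein", "id"))


def read_transcript_table(
    path: str | Path, orientation: str = "pathogenic_high"
) -> ScoreTable:
    """Read a transcript-variant table (transcript id, variant, score).

    Same row shape as the long-form dialect, keyed by transcript identifier.
    """
    return _read_long_form(Path(path), orientation,
                           ("transcript_id", "transcript", "id"))


def read_matrix_table(
    path: str | Path, orientation: str = "pathogenic_low"
) -> ScoreTable:
    """Read a position x substitution score matrix.

    One row per position with a reference amino acid; one column per
    substitute amino acid (all 20 must be named in the header).  The
    self-substitution cell is ignored; empty cells mean the substitution is
    unavailable.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    aa_cols = [c for c in df.columns if c.strip().upper() in set(AA1)]
    if len(aa_cols) != 20:
        raise FormatError(
            f"{path}: header must name all 20 amino-acid columns, "
            f"found {len(aa_cols)}")
    lower = {c.lower(): c for c in df.columns}
    pos_col = next((lower[c] for c in ("position", "pos") if c in lower), None)
    ref_col = next((lower[c] for c in ("ref", "reference", "aa", "wildtype")
                    if c in lower), None)
    if not (pos_col and ref_col):
        raise FormatError(f"{path}: need position and ref columns")
    entries: dict[tuple[int, str, str], float] = {}
    for i, row in df.iterrows():
        ref = str(row[ref_col]).strip().upper()
        if ref not in {c.strip().upper() for c in aa_cols}:
            raise FormatError(
                f"{path} row {i + 2}: reference {ref!r} not in header")
        pos = int(row[pos_col])
        for c in aa_cols:
            alt = c.strip().upper()
            if alt == ref:
                continue  # self cell ignored
            val = row[c]
            if pd.isna(val):
                continue  # unavailable substitution
            score = float(val)
            if not 0.0 <= score <= 1.0:
                raise FormatError(
                    f"{path} row {i + 2}: score {score} outside [0, 1]")
            entries[(pos, ref, alt)] = score
    return ScoreTable(path.stem, orientation, entries)


def write_variant_table(table: ScoreTable, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["protein_id", "variant", "score"]) + "\n")
        for (pos, ref, alt), s in sorted(table.entries.items()):
            fh.write(sep.join([table.protein_id, f"{ref}{pos}{alt}",
                               f"{s:.6f}"]) + "\n")


def write_transcript_table(
    table: ScoreTable, path: str | Path, transcript_id: str | None = None
) -> None:
    path = Path(path)
    sep = _sep_for(path)
    tid = transcript_id or f"ENST_{table.protein_id}"
    with open(path, "w") as fh:
        fh.write(sep.join(["transcript_id", "variant", "score"]) + "\n")
        for (pos, ref, alt), s in sorted(table.entries.items()):
            fh.write(sep.join([tid, f"{ref}{pos}{alt}", f"{s:.6f}"]) + "\n")


def write_matrix_table(table: ScoreTable, path: str | Path) -> None:
    """Write the matrix dialect; the self cell and unavailable substitutions
    are left blank."""
    path = Path(path)
    sep = _sep_for(path)
    by_pos: dict[int, tuple[str, dict[str, float]]] = {}
    for (pos, ref, alt), s in table.entries.items():
        ref0, row = by_pos.setdefault(pos, (ref, {}))
        if ref0 != ref:
            raise ValueError(f"conflicting reference at position {pos}")
        row[alt] = s
    with open(path, "w") as fh:
        fh.write(sep.join(["position", "ref", *AA1]) + "\n")
        for pos in sorted(by_pos):
            ref, row = by_pos[pos]
            cells = ["" if aa == ref or aa not in row else f"{row[aa]:.6f}"
                     for aa in AA1]
            fh.write(sep.join([str(pos), ref, *cells]) + "\n")


def residue_means(table: ScoreTable, structure: Structure) -> ResidueMeans:
    """Average each residue's available non-synonymous substitution scores.

    Positions are matched on the author residue number.  Residues with no
    entries get ``mean_score=None`` and are excluded from every downstream
    mean.  Reference-amino-acid disagreements between table and structure
    are reported, not fatal, and do not drop the residue.
    """
    by_pos: dict[int, list[tuple[str, float]]] = {}
    for (pos, ref, alt), s in table.entries.items():
        by_pos.setdefault(pos, []).append((ref, s))
    out: dict[ResidueId, ResidueScore] = {}
    mismatches: list[tuple[int, str, str]] = []
    for rid in structure.residues:
        rows = by_pos.get(rid.number, [])
        refs = {ref for ref, _ in rows}
        for ref in sorted(refs):
            if ref != rid.aa:
                mismatches.append((rid.number, ref, rid.aa))
        if rows:
            vals = np.array([s for _, s in rows], dtype=float)
            out[rid] = ResidueScore(rid, float(vals.mean()), len(vals))
        else:
            out[rid] = ResidueScore(rid, None, 0)
    if mismatches:
        logger.warning(
            "%s: %d positions with reference mismatches vs structure %s",
            table.protein_id, len(mismatches), structure.id,
        )
    return ResidueMeans(table.protein_id, table.orientation, out, mismatches)


def export_residue_means_tsv(means: ResidueMeans, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tchain\tposition\taa\tmean\tn\n")
        for rid, rs in means.scores.items():
            val = "" if rs.mean_score is None else f"{rs.mean_score:.6f}"
            fh.write(
                f"{means.protein_id}\t{rid.chain}\t{rid.number}\t{rid.aa}"
                f"\t{val}\t{rs.n_substitutions}\n"
            )
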