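"""Aggregate per-substitution pathogenicity scores to per-residue means.

A long-form variant table (one row per substitution, AlphaMissense-style)
is written and read back, then averaged per residue over all available
non-synonymous substitutions.  Missing positions stay missing; reference
mismatches are reported, not fatal.
"""

import tempfile
from pathlib import Path

from tunnelgrad import (
    CohortSpec,
    read_variant_table,
    residue_means,
)
from tunnelgrad.scores import write_variant_table
from tunnelgrad.synthetic import make_scores, make_structure

spec = CohortSpec(n_residues=120, n_helices=6, cofactor_atoms=8, seed=42)
structure, _ = make_structure(spec, index=0)
table = make_scores(spec, structure, structure.cofactor_centroid(), index=0)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "scores.tsv"
    write_variant_table(table, path)
    back = read_variant_table(path)

means = residue_means(back, structure)
scored = [s for s in means.scores.values() if s.mean_score is not None]
print(f"{len(back.entries)} substitution scores "
      f"-> {len(scored)} residue means "
      f"({sum(s.n_substitutions for s in scored)} substitutions used)")
first = scored[0]
print(f"residue {first.residue.label()}: mean {first.mean_score:.3f} "
      f"over {first.n_substitutions} substitutions")
print(f"reference mismatches: {len(means.mismatches)}")

# Each residue's mean is the plain arithmetic average of its (up to 19)
# available substitution scores; n_substitutions makes the averaging
# convention auditable.
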