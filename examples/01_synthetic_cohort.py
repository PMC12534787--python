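"""Materialise a small synthetic study cohort on disk.

Each protein gets a PDB model (helix-bundle shell with a buried pseudo-heme
and one open channel), a tunnel-profile JSON, and three pathogenicity score
tables — one per supported dialect, the matrix dialect on the inverse
(low = pathogenic) scale.  The manifest ties everything together for the
pipeline.
"""

import tempfile
from pathlib import Path

from tunnelgrad import CohortSpec, make_cohort

with tempfile.TemporaryDirectory() as tmp:
    spec = CohortSpec(n_proteins=2, n_residues=120, n_helices=6,
                      cofactor_atoms=8, seed=42)
    manifest = make_cohort(spec, Path(tmp) / "cohort")
    print(f"cohort manifest: {manifest.name}")
    for path in sorted(manifest.parent.rglob("*")):
        if path.is_file():
            print(f"  {path.relative_to(manifest.parent)}"
                  f"  ({path.stat().st_size} bytes)")

# The per-protein directories hold everything the pipeline consumes; the
# byte sizes show these are small, fully regenerable text fixtures.
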