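"""End-to-end orchestration: structures + tunnels + scores -> region report.

The pipeline is deliberately split into a pure in-memory core
(:func:`run_cohort`) and an IO wrapper (:func:`run_pipeline`) driven by a
YAML/JSON run configuration, so tests and library users can run cohorts
without touching the filesystem.

Proteins whose tunnel stage yields nothing are reported and excluded from
the region statistics (the analysis is defined on the reduced cohort of
proteins that do contain tunnels); per-protein failures are logged and skip
the protein, never the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import residue_sets as rsets
from . import scores as sc
from . import stats as st
from .errors import TunnelgradError
from .structures import Structure, read_structure
from .tunnels import Tunnel, TunnelParams, find_tunnels, read_mole_tunnels

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ToolConfig:
    name: str
    dialect: str        # variant | matrix | transcript
    orientation: str    # pathogenic_high | pathogenic_low


@dataclasses.dataclass
class ProteinEntry:
    id: str
    structure: str                 # PDB path
    tunnels: str                   # profile JSON path, or "compute"
    scores: dict[str, str]         # tool name -> table path


@dataclasses.dataclass
class RunConfig:
    proteins: list[ProteinEntry]
    tools: list[ToolConfig]
    tunnel_params: TunnelParams = dataclasses.field(default_factory=TunnelParams)
    spacing: float = 0.5
    n_atoms: int = 5
    adherence_level: str = "per_protein"
    bins: int = 10
    cofactor_code: str = "HEM"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        tool_names = {t.name for t in self.tools}
        for p in self.proteins:
            if not p.scores:
                raise ValueError(f"protein {p.id}: no score tables configured")
            unknown = set(p.scores) - tool_names
            if unknown:
                raise ValueError(f"protein {p.id}: unknown tools {unknown}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration (e.g. a cohort manifest)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    tools = [ToolConfig(**t) for t in doc["tools"]]
    proteins = [ProteinEntry(**p) for p in doc["proteins"]]
    kwargs = {k: doc[k] for k in
              ("spacing", "n_atoms", "adherence_level", "bins",
               "cofactor_code", "out_dir", "seed") if k in doc}
    params = TunnelParams(**doc.get("tunnel_params", {}))
    return RunConfig(proteins, tools, params, **kwargs)


_READERS = {
    "variant": sc.read_variant_table,
    "matrix": sc.read_matrix_table,
    "transcript": sc.read_transcript_table,
}


@dataclasses.dataclass
class ProteinData:
    """In-memory inputs for one protein."""

    structure: Structure
    tunnels: list[Tunnel]
    tables: dict[str, sc.ScoreTable]


@dataclasses.dataclass
class CohortReport:
    summaries: dict[str, list[st.RegionSummary]]       # tool -> all proteins
    adherence: dict[str, st.AdherenceResult]
    tests: dict[str, list[st.PairedTestResult]]
    frequency_profiles: dict[str, "np.typing.ArrayLike"]
    group_means: dict[str, "np.typing.ArrayLike"]
    heatmaps: dict[str, dict]
    no_tunnel_proteins: list[str]
    failed_proteins: list[str]
    n_proteins: int
    residue_sets: dict[str, dict[str, rsets.ResidueSet]]
    residue_means: dict[str, dict[str, sc.ResidueMeans]]  # tool -> pid -> means

    def to_dict(self) -> dict:
        def _round(x, nd=10):
            return None if x is None else round(float(x), nd)

        out: dict = {
            "n_proteins": self.n_proteins,
            "no_tunnel_proteins": sorted(self.no_tunnel_proteins),
            "failed_proteins": sorted(self.failed_proteins),
            "tools": {},
        }
        for tool, summaries in sorted(self.summaries.items()):
            adh = self.adherence[tool]
            out["tools"][tool] = {
                "region_means": {
                    s.protein_id: {} for s in summaries
                },
                "adherence": {
                    "level": adh.level,
                    "n_total": adh.n_total,
                    "n_adhering": adh.n_adhering,
                    "rate_percent": _round(adh.rate, 4),
                    "excluded": sorted(adh.excluded),
                },
                "paired_tests": [
                    {
                        "comparison": list(t.comparison),
                        "t": _round(t.t_statistic, 6),
                        "p": _round(t.p_value, 12),
                        "n_pairs": t.n_pairs,
                        "stars": t.stars,
                        "degenerate": t.degenerate,
                    }
                    for t in self.tests[tool]
                ],
                "group_means": {
                    aa: {
                        r: _round(v, 6)
                        for r, v in row.items()
                        if v == v  # drop NaN cells
                    }
                    for aa, row in self.group_means[tool].to_dict("index").items()
                },
                "heatmap_counts": {
                    region: df.to_dict("index")
                    for region, df in self.heatmaps[tool].items()
                },
            }
            for s in summaries:
                out["tools"][tool]["region_means"][s.protein_id][s.region] = {
                    "mean": _round(s.mean_score, 8),
                    "n_residues": s.n_residues,
                    "n_missing": s.n_missing,
                }
        out["frequency_profiles"] = {
            region: {aa: _round(v, 6) for aa, v in profile.items()}
            for region, profile in sorted(self.frequency_profiles.items())
        }
        return out


def run_cohort(
    proteins: dict[str, ProteinData],
    orientations: dict[str, str],
    spacing: float = 0.5,
    n_atoms: int = 5,
    adherence_level: str = "per_protein",
    bins: int = 10,
    no_tunnel: list[str] | None = None,
    failed: list[str] | None = None,
) -> CohortReport:
    """Region statistics for an in-memory cohort.

    ``proteins`` maps protein id to its inputs; ``orientations`` maps tool
    name to scale orientation.  Proteins without tunnels must already be
    excluded from ``proteins`` (list them in ``no_tunnel``).
    """
    if not proteins:
        raise ValueError("empty cohort: no protein passed all input stages")
    sets_by_protein: dict[str, dict[str, rsets.ResidueSet]] = {}
    for pid, pd_ in proteins.items():
        sets_by_protein[pid] = rsets.build_region_sets(
            pd_.structure, pd_.tunnels, spacing, n_atoms)

    # region amino-acid composition is score-independent
    freq: dict[str, object] = {}
    for region in rsets.REGIONS:
        members = []
        for pid, sets in sets_by_protein.items():
            members.extend(sets[region].members)
        counts = pd.Series(0.0, index=list(sc.AA1))
        for rid in members:
            if rid.aa in counts.index:
                counts[rid.aa] += 1
        freq[region] = counts / max(counts.sum(), 1) * 100.0

    summaries: dict[str, list[st.RegionSummary]] = {}
    means_by_tool: dict[str, dict[str, sc.ResidueMeans]] = {}
    adh: dict[str, st.AdherenceResult] = {}
    tests: dict[str, list[st.PairedTestResult]] = {}
    group_means: dict[str, object] = {}
    heatmaps: dict[str, dict] = {}
    for tool, orientation in orientations.items():
        tool_summaries: list[st.RegionSummary] = []
        cohort_pairs = []
        means_by_tool[tool] = {}
        for pid, pd_ in proteins.items():
            if tool not in pd_.tables:
                continue
            means = sc.residue_means(pd_.tables[tool], pd_.structure)
            means_by_tool[tool][pid] = means
            tool_summaries.extend(
                st.region_summaries(means, sets_by_protein[pid]))
            cohort_pairs.append((means, sets_by_protein[pid]))
        if not cohort_pairs:
            continue
        summaries[tool] = tool_summaries
        gm = st.per_aa_group_means(cohort_pairs)
        group_means[tool] = gm
        heatmaps[tool] = st.score_frequency_heatmap(cohort_pairs, bins)
        adh[tool] = st.adherence(
            tool_summaries, orientation, adherence_level, group_means=gm)
        tests[tool] = st.paired_tests(tool_summaries)
    return CohortReport(
        summaries, adh, tests, freq, group_means, heatmaps,
        no_tunnel or [], failed or [], len(proteins),
        sets_by_protein, means_by_tool,
    )


def run_pipeline(config: RunConfig) -> CohortReport:
    """Load every configured input, run the cohort analysis, and (when an
    output directory is configured) write the TSV/JSON report bundle."""
    orientations = {t.name: t.orientation for t in config.tools}
    dialects = {t.name: t.dialect for t in config.tools}
    proteins: dict[str, ProteinData] = {}
    no_tunnel: list[str] = []
    failed: list[str] = []
    for entry in config.proteins:
        try:
            structure = read_structure(entry.structure, config.cofactor_code)
            structure.id = entry.id  # the manifest id, not the file stem
            if entry.tunnels == "compute":
                tunnels = find_tunnels(structure, config.tunnel_params,
                                       seed=config.seed)
            else:
                tunnels = read_mole_tunnels(entry.tunnels)
            if not tunnels:
                logger.info("%s: no tunnels; excluded from region statistics",
                            entry.id)
                no_tunnel.append(entry.id)
                continue
            tables = {}
            for tool, path in entry.scores.items():
                reader = _READERS[dialects[tool]]
                table = reader(path, orientation=orientations[tool])
                tables[tool] = dataclasses.replace(table,
                                                   protein_id=structure.id)
            proteins[entry.id] = ProteinData(structure, tunnels, tables)
        except (TunnelgradError, OSError, ValueError) as exc:
            logger.error("%s: %s; protein skipped", entry.id, exc)
            failed.append(entry.id)
    report = run_cohort(
        proteins, orientations, config.spacing, config.n_atoms,
        config.adherence_level, config.bins, no_tunnel, failed,
    )
    if config.out_dir:
        write_report_bundle(report, config)
    return report


def write_report_bundle(report: CohortReport, config: RunConfig) -> Path:
    """Write report.json plus per-protein and cohort TSV tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    with open(out / "region_means.tsv", "w") as fh:
        fh.write("tool\tprotein_id\tregion\tmean\tn_residues\tn_missing\n")
        for tool, summaries in sorted(report.summaries.items()):
            for s in summaries:
                val = "" if s.mean_score is None else f"{s.mean_score:.8f}"
                fh.write(f"{tool}\t{s.protein_id}\t{s.region}\t{val}"
                         f"\t{s.n_residues}\t{s.n_missing}\n")
    per_protein = out / "per_protein"
    per_protein.mkdir(exist_ok=True)
    for pid, sets in report.residue_sets.items():
        rsets.export_residue_sets_tsv(sets, pid,
                                      per_protein / f"{pid}_sets.tsv")
    for tool, by_pid in report.residue_means.items():
        for pid, means in by_pid.items():
            sc.export_residue_means_tsv(
                means, per_protein / f"{pid}_{tool}_means.tsv")
    return out / "report.json"
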