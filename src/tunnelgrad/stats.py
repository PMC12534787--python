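"""Region-level statistics of per-residue pathogenicity.

Quantities computed here mirror the standard presentation of a
protein → tunnel → cofactor pathogenicity gradient:

* per-protein per-region mean scores,
* amino-acid frequency profiles of each region,
* per-amino-acid group averages (amino acid x region matrix),
* score-frequency histograms (region x amino acid x score bin),
* adherence — how many units (proteins, or amino-acid types) show the
  strict monotone pattern protein < tunnel < cofactor (reversed for
  inverse-scaled tools),
* paired t-tests across proteins for (protein, tunnel) and
  (tunnel, cofactor), with the star tiers **P<.05, ***P<.005, ****P<.0005.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .residue_sets import REGIONS, ResidueSet
from .scores import ResidueMeans
from .structures import AA1

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("protein", "tunnel"), ("tunnel", "cofactor"))
#: (p threshold, stars); checked in order, first match wins
DEFAULT_TIERS = ((0.0005, "****"), (0.005, "***"), (0.05, "**"))


@dataclasses.dataclass
class RegionSummary:
    protein_id: str
    region: str
    mean_score: float | None
    n_residues: int
    n_missing: int


@dataclasses.dataclass
class PairedTestResult:
    comparison: tuple[str, str]
    t_statistic: float
    p_value: float
    n_pairs: int
    stars: str
    degenerate: bool = False


@dataclasses.dataclass
class AdherenceResult:
    level: str  # per_protein | per_amino_acid
    n_total: int
    n_adhering: int
    rate: float  # percent
    excluded: list[str]  # units skipped for missing regions


def region_summaries(
    means: ResidueMeans, sets: dict[str, ResidueSet]
) -> list[RegionSummary]:
    """One summary per region: mean over the region's scored residues."""
    out = []
    for region in REGIONS:
        if region not in sets:
            continue
        rs = sets[region]
        vals = []
        missing = 0
        for rid in rs.members:
            sc = means.scores.get(rid)
            if sc is None or sc.mean_score is None:
                missing += 1
            else:
                vals.append(sc.mean_score)
        if vals:
            mean = float(np.mean(vals))
        else:
            mean = None
            logger.warning("%s/%s: no scored residues in region",
                           means.protein_id, region)
        out.append(RegionSummary(means.protein_id, region, mean,
                                 len(rs.members), missing))
    return out


def aa_frequency_profile(residue_set: ResidueSet) -> pd.Series:
    """Percentage of set members per amino-acid type; sums to 100."""
    if not residue_set.members:
        raise ValueError("cannot profile an empty residue set")
    counts = pd.Series(0.0, index=list(AA1))
    for rid in residue_set.members:
        if rid.aa in counts.index:
            counts[rid.aa] += 1
    return counts / counts.sum() * 100.0


def _iter_cohort(
    cohort: Iterable[tuple[ResidueMeans, dict[str, ResidueSet]]]
) -> Iterable[tuple[ResidueMeans, dict[str, ResidueSet]]]:
    return cohort


def per_aa_group_means(
    cohort: Iterable[tuple[ResidueMeans, dict[str, ResidueSet]]]
) -> pd.DataFrame:
    """Amino acid x region matrix of mean residue scores over the cohort.

    A cell is NaN when that amino acid never occurs (scored) in that region
    anywhere in the cohort — absence is meaningful and is reported as such.
    """
    sums = pd.DataFrame(0.0, index=list(AA1), columns=list(REGIONS))
    counts = pd.DataFrame(0, index=list(AA1), columns=list(REGIONS))
    for means, sets in _iter_cohort(cohort):
        for region in REGIONS:
            if region not in sets:
                continue
            for rid in sets[region].members:
                sc = means.scores.get(rid)
                if sc is None or sc.mean_score is None or rid.aa not in AA1:
                    continue
                sums.loc[rid.aa, region] += sc.mean_score
                counts.loc[rid.aa, region] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts
    return out.where(counts > 0)


def score_frequency_heatmap(
    cohort: Iterable[tuple[ResidueMeans, dict[str, ResidueSet]]],
    bins: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per region, counts of residue mean scores per amino acid per
    equal-width bin over [0, 1] (final bin right-closed, so 1.0 lands in it).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f}" + ("]" if i == bins - 1 else ")")
              for i in range(bins)]
    out = {
        region: pd.DataFrame(0, index=list(AA1), columns=labels)
        for region in REGIONS
    }
    for means, sets in _iter_cohort(cohort):
        for region in REGIONS:
            if region not in sets:
                continue
            for rid in sets[region].members:
                sc = means.scores.get(rid)
                if sc is None or sc.mean_score is None or rid.aa not in AA1:
                    continue
                b = int(np.searchsorted(edges, sc.mean_score, side="right")) - 1
                b = min(max(b, 0), bins - 1)
                out[region].iloc[out[region].index.get_loc(rid.aa), b] += 1
    return out


def _adheres(p: float, t: float, c: float, orientation: str,
             tolerance: float) -> bool:
    if orientation == "pathogenic_high":
        return (t - p) > tolerance and (c - t) > tolerance
    return (p - t) > tolerance and (t - c) > tolerance


def adherence(
    summaries: Sequence[RegionSummary] | None,
    orientation: str,
    level: str = "per_protein",
    tolerance: float = 0.0,
    group_means: pd.DataFrame | None = None,
) -> AdherenceResult:
    """Fraction of units following the monotone pathogenicity pattern.

    ``per_protein`` units are proteins (using their region mean scores);
    ``per_amino_acid`` units are amino-acid types (using the cohort's
    amino acid x region matrix, passed as ``group_means``).  The pattern is
    strict protein < tunnel < cofactor for ``pathogenic_high`` scales and
    strictly reversed for ``pathogenic_low``.  Units with any missing region
    value are excluded from the denominator and listed in ``excluded``.
    """
    units: list[tuple[str, float | None, float | None, float | None]] = []
    if level == "per_protein":
        if not summaries:
            raise ValueError("per_protein adherence needs region summaries")
        by_protein: dict[str, dict[str, float | None]] = {}
        for s in summaries:
            by_protein.setdefault(s.protein_id, {})[s.region] = s.mean_score
        for pid, regions in by_protein.items():
            units.append((pid, regions.get("protein"), regions.get("tunnel"),
                          regions.get("cofactor")))
    elif level == "per_amino_acid":
        if group_means is None:
            raise ValueError("per_amino_acid adherence needs group_means")
        for aa, row in group_means.iterrows():
            vals = [row.get(r) for r in REGIONS]
            vals = [None if v is None or (isinstance(v, float) and math.isnan(v))
                    else float(v) for v in vals]
            units.append((str(aa), *vals))
    else:
        raise ValueError(f"unknown adherence level {level!r}")

    excluded = [u for u, p, t, c in units if None in (p, t, c)]
    eligible = [(u, p, t, c) for u, p, t, c in units if None not in (p, t, c)]
    if not eligible:
        raise ValueError("no unit has all three region values")
    n_adh = sum(
        _adheres(p, t, c, orientation, tolerance) for _, p, t, c in eligible
    )
    return AdherenceResult(
        level, len(eligible), n_adh, 100.0 * n_adh / len(eligible), excluded
    )


def stars_for(p_value: float,
              tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS) -> str:
    for thr, s in sorted(tiers):
        if p_value < thr:
            return s
    return "ns"


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t-test of b vs a: t = mean(d)/(sd(d)/sqrt(n)), d=b-a,
    with n-1 degrees of freedom.  Returns (t, p, degenerate); an all-zero
    spread of differences is degenerate and reported as p=1."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        return float("nan"), 1.0, True
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), False


def paired_tests(
    summaries: Sequence[RegionSummary],
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS,
) -> list[PairedTestResult]:
    """Paired t-tests across proteins for each (region A, region B) pair.

    Pairs are proteins with both regions scored; the test is two-sided on
    the per-protein differences B - A.
    """
    by_protein: dict[str, dict[str, float | None]] = {}
    for s in summaries:
        by_protein.setdefault(s.protein_id, {})[s.region] = s.mean_score
    out = []
    for a_region, b_region in comparisons:
        a_vals, b_vals = [], []
        for regions in by_protein.values():
            a, b = regions.get(a_region), regions.get(b_region)
            if a is not None and b is not None:
                a_vals.append(a)
                b_vals.append(b)
        if len(a_vals) < 2:
            raise ValueError(
                f"comparison {a_region} vs {b_region}: fewer than 2 pairs")
        t, p, degenerate = paired_t(np.array(a_vals), np.array(b_vals))
        out.append(PairedTestResult(
            (a_region, b_region), t, p, len(a_vals),
            "ns" if degenerate else stars_for(p, tiers), degenerate,
        ))
    return out
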