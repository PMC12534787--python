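import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from tunnelgrad.residue_sets import ResidueSet
from tunnelgrad.scores import ResidueMeans, ResidueScore
from tunnelgrad.stats import (
    DEFAULT_TIERS,
    RegionSummary,
    aa_frequency_profile,
    adherence,
    paired_t,
    paired_tests,
    per_aa_group_means,
    region_summaries,
    score_frequency_heatmap,
    stars_for,
)
from tunnelgrad.structures import ResidueId


def rid(n, aa="G"):
    return ResidueId("A", n, "", aa)


def residue_set(region, rids):
    return ResidueSet(region, list(rids), {r: ("x", 0.0) for r in rids})


def means_of(values, orientation="pathogenic_high", pid="P1"):
    """values: {ResidueId: mean or None}."""
    scores = {
        r: ResidueScore(r, v, 0 if v is None else 19)
        for r, v in values.items()
    }
    return ResidueMeans(pid, orientation, scores, [])


class TestRegionSummaries:
    def test_region_means_arithmetic(self):
        rids = [rid(i) for i in range(1, 5)]
        vals = dict(zip(rids, [0.1, 0.2, 0.3, 0.4]))
        sets = {
            "protein": residue_set("protein", rids),
            "tunnel": residue_set("tunnel", rids[2:]),
            "cofactor": residue_set("cofactor", rids[3:]),
        }
        out = {s.region: s for s in region_summaries(means_of(vals), sets)}
        assert out["protein"].mean_score == pytest.approx(0.25)
        assert out["tunnel"].mean_score == pytest.approx(0.35)
        assert out["cofactor"].mean_score == pytest.approx(0.4)

    def test_subset_with_same_scores_recomputes(self, rng):
        rids = [rid(i) for i in range(1, 31)]
        vals = {r: float(v) for r, v in zip(rids, rng.uniform(size=30))}
        tunnel = rids[5:20]
        cof = rids[10:15]  # subset of the tunnel set
        sets = {"tunnel": residue_set("tunnel", tunnel),
                "cofactor": residue_set("cofactor", cof)}
        out = {s.region: s for s in region_summaries(means_of(vals), sets)}
        assert out["cofactor"].mean_score == pytest.approx(
            np.mean([vals[r] for r in cof]))

    def test_all_missing_region(self):
        rids = [rid(i) for i in range(1, 4)]
        vals = {r: None for r in rids}
        sets = {"protein": residue_set("protein", rids)}
        (s,) = region_summaries(means_of(vals), sets)
        assert s.mean_score is None
        assert s.n_missing == s.n_residues == 3


class TestFrequencyProfile:
    def test_counting(self):
        rs = residue_set("tunnel", [rid(1, "L"), rid(2, "L"),
                                    rid(3, "F"), rid(4, "R")])
        profile = aa_frequency_profile(rs)
        assert profile["L"] == pytest.approx(50.0)
        assert profile["F"] == pytest.approx(25.0)
        assert profile["R"] == pytest.approx(25.0)

    def test_sums_to_100(self, rng):
        from tunnelgrad.structures import AA1
        rids = [rid(i, AA1[rng.integers(20)]) for i in range(1, 80)]
        assert aa_frequency_profile(residue_set("protein", rids)).sum() == \
            pytest.approx(100.0, abs=1e-9)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            aa_frequency_profile(residue_set("tunnel", []))


class TestGroupMeans:
    def test_single_glycine_cell(self):
        g = rid(1, "G")
        vals = {g: 0.8}
        sets = {"cofactor": residue_set("cofactor", [g])}
        gm = per_aa_group_means([(means_of(vals), sets)])
        assert gm.loc["G", "cofactor"] == pytest.approx(0.8)

    def test_absent_combination_is_missing(self):
        g = rid(1, "G")
        sets = {"tunnel": residue_set("tunnel", [g])}
        gm = per_aa_group_means([(means_of({g: 0.5}), sets)])
        assert math.isnan(gm.loc["W", "tunnel"])

    def test_matches_pandas_groupby(self, rng):
        from tunnelgrad.structures import AA1
        cohort = []
        rows = []
        for p in range(4):
            rids = [rid(i, AA1[rng.integers(20)]) for i in range(1, 40)]
            vals = {r: float(v) for r, v in zip(rids, rng.uniform(size=39))}
            tunnel = [r for r in rids if rng.uniform() < 0.4]
            sets = {"protein": residue_set("protein", rids),
                    "tunnel": residue_set("tunnel", tunnel)}
            cohort.append((means_of(vals, pid=f"P{p}"), sets))
            for r in rids:
                rows.append(("protein", r.aa, vals[r]))
            for r in tunnel:
                rows.append(("tunnel", r.aa, vals[r]))
        gm = per_aa_group_means(cohort)
        df = pd.DataFrame(rows, columns=["region", "aa", "v"])
        oracle = df.groupby(["region", "aa"])["v"].mean()
        for (region, aa), v in oracle.items():
            assert gm.loc[aa, region] == pytest.approx(v)


class TestHeatmap:
    def _cohort(self, values):
        rids = [rid(i + 1, "G") for i in range(len(values))]
        vals = dict(zip(rids, values))
        sets = {"protein": residue_set("protein", rids)}
        return [(means_of(vals), sets)]

    def test_score_one_lands_in_last_bin(self):
        hm = score_frequency_heatmap(self._cohort([1.0]), bins=10)
        assert hm["protein"].iloc[:, -1].sum() == 1

    def test_counts_conserve_scored_residues(self, rng):
        values = list(rng.uniform(size=25)) + [None] * 5
        hm = score_frequency_heatmap(self._cohort(values), bins=10)
        assert hm["protein"].values.sum() == 25

    def test_matches_exhaustive_recount(self, rng):
        values = [float(v) for v in rng.uniform(size=40)]
        hm = score_frequency_heatmap(self._cohort(values), bins=10)
        counts = hm["protein"].loc["G"].values
        edges = np.linspace(0, 1, 11)
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            expected = sum(
                1 for v in values
                if (lo <= v < hi) or (b == 9 and v == 1.0)
            )
            assert counts[b] == expected


class TestAdherence:
    def _summaries(self, p, t, c, pid="P1"):
        return [RegionSummary(pid, "protein", p, 10, 0),
                RegionSummary(pid, "tunnel", t, 5, 0),
                RegionSummary(pid, "cofactor", c, 3, 0)]

    def test_monotone_protein_adheres(self):
        res = adherence(self._summaries(0.3, 0.5, 0.7), "pathogenic_high")
        assert res.n_adhering == 1 and res.rate == 100.0

    def test_same_values_fail_under_inverse_orientation(self):
        res = adherence(self._summaries(0.3, 0.5, 0.7), "pathogenic_low")
        assert res.n_adhering == 0

    def test_missing_region_excluded_from_denominator(self):
        summaries = (self._summaries(0.3, 0.5, 0.7, "P1")
                     + self._summaries(0.3, None, 0.7, "P2"))
        res = adherence(summaries, "pathogenic_high")
        assert res.n_total == 1
        assert res.excluded == ["P2"]

    def test_per_amino_acid_level(self):
        gm = pd.DataFrame(
            {"protein": [0.2, 0.5], "tunnel": [0.3, 0.4],
             "cofactor": [0.4, np.nan]},
            index=["G", "W"],
        )
        res = adherence(None, "pathogenic_high", level="per_amino_acid",
                        group_means=gm)
        assert res.n_total == 1 and res.n_adhering == 1
        assert res.excluded == ["W"]

    def test_strict_inequality_zero_tolerance(self):
        res = adherence(self._summaries(0.3, 0.3, 0.7), "pathogenic_high")
        assert res.n_adhering == 0
        res = adherence(self._summaries(0.3, 0.31, 0.7), "pathogenic_high")
        assert res.n_adhering == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(
        hst.tuples(hst.floats(0.01, 0.99), hst.floats(0.01, 0.99),
                   hst.floats(0.01, 0.99)),
        min_size=1, max_size=12))
    def test_inversion_symmetry(self, triples):
        """Replacing every score s by 1-s and flipping the orientation leaves
        the adherence result identical."""
        summaries, flipped = [], []
        for i, (p, t, c) in enumerate(triples):
            summaries += self._summaries(p, t, c, f"P{i}")
            flipped += self._summaries(1 - p, 1 - t, 1 - c, f"P{i}")
        a = adherence(summaries, "pathogenic_high")
        b = adherence(flipped, "pathogenic_low")
        assert (a.n_adhering, a.n_total) == (b.n_adhering, b.n_total)


class TestPairedT:
    def test_closed_form_differences_123(self):
        t, p, degenerate = paired_t(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert not degenerate
        assert t == pytest.approx(2 * math.sqrt(3))
        assert p == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), 2))

    def test_all_zero_differences_degenerate(self):
        t, p, degenerate = paired_t(np.ones(4), np.ones(4))
        assert degenerate and p == 1.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            t, p, _ = paired_t(a, b)
            ref = sps.ttest_rel(b, a)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0]), np.array([2.0]))


class TestPairedTests:
    def _cohort_summaries(self, rng, n=10):
        out = []
        for i in range(n):
            p, t, c = rng.uniform(0.2, 0.4), rng.uniform(0.3, 0.5), \
                rng.uniform(0.4, 0.6)
            out += [RegionSummary(f"P{i}", "protein", p, 10, 0),
                    RegionSummary(f"P{i}", "tunnel", t, 5, 0),
                    RegionSummary(f"P{i}", "cofactor", c, 3, 0)]
        return out

    def test_default_comparisons_present(self, rng):
        results = paired_tests(self._cohort_summaries(rng))
        assert [r.comparison for r in results] == [
            ("protein", "tunnel"), ("tunnel", "cofactor")]
        assert all(r.n_pairs == 10 for r in results)

    def test_pairs_require_both_regions(self, rng):
        summaries = self._cohort_summaries(rng)
        summaries.append(RegionSummary("Px", "protein", 0.3, 10, 0))
        summaries.append(RegionSummary("Px", "tunnel", None, 5, 5))
        results = paired_tests(summaries)
        assert results[0].n_pairs == 10  # Px has no tunnel mean


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.04, "**"), (0.051, "ns"), (0.004, "***"), (0.0004, "****"),
        (0.9, "ns"),
    ])
    def test_tier_assignment(self, p, stars):
        assert stars_for(p, DEFAULT_TIERS) == stars
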