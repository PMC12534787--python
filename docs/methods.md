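# Methods

## The analysis

Given (i) a protein structure with one buried cofactor group, (ii) one or
more tunnel centerlines from the cofactor to the surface, and (iii) a table
of per-substitution missense pathogenicity scores, the pipeline compares
predicted pathogenicity across three regions:

* **protein** — every residue of the chain;
* **tunnel** — the union, over all tunnels and over centerline sample
  points placed every `spacing` Å (default 0.5 Å, endpoints always
  included), of the residues owning the `n_atoms` (default 5) protein
  heavy atoms closest to each point. Because the atoms are mapped to
  parent residues and deduplicated, each sample point contributes between
  one and five residues;
* **cofactor** — the analogous non-redundant union over cofactor atoms of
  the residues owning the five closest protein heavy atoms to each atom.

Residue-level pathogenicity is the arithmetic mean over all *available*
non-synonymous substitutions at that position (at most 19; the count is
kept alongside the mean so the averaging convention is auditable).
Positions absent from the score table stay missing and are excluded from
every downstream mean. Region means are computed per protein over the
scored members of each set.

Cohort-level quantities: amino-acid frequency profiles per region
(percentages summing to 100), per-amino-acid group means (amino acid x
region matrix, with genuinely absent combinations reported as missing),
score-frequency histograms (equal-width bins on [0, 1], last bin
right-closed), adherence, and paired t-tests.

**Adherence.** A unit adheres when its region means satisfy the strict
chain mean(protein) < mean(tunnel) < mean(cofactor); both inequalities are
reversed for tools with an inverse scale (`pathogenic_low`). The unit is a
protein by default; a per-amino-acid mode applies the same rule to the
group-mean matrix. No tolerance is imposed: a 0.01 difference counts.
Units missing any region are excluded from the denominator and listed.

**Paired tests.** For each comparison (protein vs tunnel, tunnel vs
cofactor), the differences d of per-protein region means give
t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom, two-sided
p-values from the t distribution, and tier labels \*\*p<.05, \*\*\*p<.005,
\*\*\*\*p<.0005 (an unconventional but fixed star convention). All-zero
differences are reported as degenerate with p = 1. Raw p-values only; no
multiple-testing correction is applied.

Scale orientation is configuration, never inferred from the data, and no
score is ever rescaled or inverted inside the aggregation layer; the
direction logic lives entirely in the adherence/test layer. This makes the
inversion symmetry exact: replacing every score s by 1-s and flipping the
declared orientation leaves adherence and significance tiers unchanged
(the t statistics flip sign).

## Structure handling

PDB files are read through gemmi. Hydrogens are excluded everywhere (the
intended inputs are heavy-atom model structures), only the first model is
used, alternate locations resolve to the highest-occupancy conformer
(first-listed on ties), and waters and HET groups other than the
configured cofactor code are ignored. Residues are identified by (chain,
author number, insertion code), never by sequence index, so gapped
numbering is safe. Score-table positions are matched on the author residue
number; reference-amino-acid mismatches are reported but do not drop the
residue.

Nearest-atom queries use a k-d tree with distance ties broken by atom
serial, making the residue sets independent of atom storage order.

## The built-in tunnel finder

When no tunnel profiles are supplied, a deliberately simple grid finder
stands in: voxelise a padded bounding box (default spacing 0.6 Å), take
the Euclidean distance transform of the atom-occupancy grid as a clearance
field, mark voxels traversable at clearance >= the interior threshold, and
run a widest-bottleneck (max-min) Dijkstra search from the most open
traversable voxel within the origin radius of the cofactor centroid.
A path is absorbed where it reaches the shell of the heavy-atom bounding
region or probe-scale open space — a tunnel ends at the surface rather
than continuing through the solvent, which is also what keeps one physical
channel from fanning out into several nominal exits. Exits closer than
the surface-cover radius to an already selected (wider) exit are treated
as the same tunnel; tunnels with bottleneck below the bottleneck radius
are discarded; voxel paths are lightly smoothed into centerlines while
radii are read off the clearance field at the original path voxels, so the
reported bottleneck is exactly the max-min search value.

Two simplifications are documented rather than hidden: radii are
centre-clearance distances to heavy-atom centres (no van der Waals radii),
and the finder makes no attempt at the Voronoi-based machinery of
dedicated tunnel tools. When real tunnel JSON is available it takes
precedence; the finder exists so the whole pipeline runs self-contained.
Profile files are re-validated on read: arc lengths and bottlenecks are
recomputed from the node coordinates, never trusted.

## Synthetic cohorts

The generator builds idealized helix-bundle shells: Calpha-only helices
(rise 1.5 Å/residue, 100 deg/residue, helix radius 2.3 Å) plus two dummy
side-chain atoms per residue pointing away from the bundle axis, arranged
in up to five concentric rings around a cavity that holds a pseudo-cofactor
(one central atom plus a staggered double ring of radius 3 Å — a
porphyrin-scale footprint). The cavity sits near the bottom of the bundle
so residue-to-cofactor distances span a wide range, and one straight
channel of known radius (default 2 Å) is opened by omitting residues along
a ray; helix ends are then trimmed so the requested residue count is met
exactly. The channel axis and its true clearances are returned as ground
truth and can be emitted as MOLE-style JSON.

Scores follow the planted model

    score(residue) = b + g * exp(-d / lambda) + Normal(0, sigma)

clipped to [0, 1], with d the residue's minimum atom distance to the
cofactor centroid. Defaults: 30 proteins of 540 residues (a cytochrome-
P450-sized chain) in 18 helices, b = 0.3, g = 0.2, lambda = 12 Å,
sigma = 0.05. The per-substitution values jitter around the residue value
with the jitter mean removed, so each residue's average equals its noisy
planted value exactly; `pathogenic_low` tables emit 1-s. Amino-acid
identities are drawn from a configurable composition (default: an
approximate vertebrate globular average), geometry depends only on the
protein index, and everything is deterministic given (seed, index).

With these defaults the planted signal is strong enough that a 30-protein
cohort shows the monotone ordering with >= 90% per-protein adherence and
both paired tests below p = .0005 in about 99% of seeds, while g = 0
cohorts keep the paired test at its nominal 5% rejection rate. The
geometry (thick shell, off-centre cavity, multi-atom cofactor) was chosen
once to realise those study conditions; lambda and the shell dimensions
control the contrast between the three regions.

Because the substitution jitter is mean-centred, the region means of a
cohort are a deterministic function of the residue-level noise alone.
`sample_region_means` exploits this to draw region means for many cohorts
without rebuilding structures or tables; it reproduces the full
make_scores -> residue_means -> region_summaries chain bitwise (a test
pins this equivalence), and the large sweeps (100-seed recovery, 1000-
cohort type-I control) run through it with the real test statistics.

What the generator does *not* emulate: real protein packing or secondary-
structure context, real score distributions of any predictor, correlated
noise between neighbouring residues, or MOLE's exact JSON schema beyond
the fields the reader consumes. Tests passing on these cohorts show the
pipeline's geometry, aggregation and statistics are correct, not that any
particular biological effect size is realistic.

A separate dense-lattice slab fixture (spacing 1.2 Å, tight at the
finder's interior threshold) plants cylindrical channels of known radius
for tunnel-finder tests.

## Numerical choices and degenerate inputs

* Distance ties in nearest-atom queries: (distance, atom serial).
* Tie-breaking in the path search: seed-shuffled insertion order on equal
  max-min values; output is deterministic given the seed.
* Histogram binning: right-open bins except the last, so a mean of 1.0 is
  counted.
* Structures with fewer protein atoms than `n_atoms`: all available atoms
  are used, with a warning.
* Tunnels with fewer than two profile nodes are skipped with a warning;
  nonpositive radii are format errors naming the node.
* Proteins whose tunnel stage yields nothing are excluded from region
  statistics and reported separately; per-protein failures skip the
  protein, never the run.
* `spacing = 0` means "use the native profile nodes" instead of
  resampling.
* Duplicate score rows: last wins, with a warning; synonymous rows are
  skipped; out-of-range scores are errors.

## Known limitations

* The finder's radii lack van der Waals corrections, so they exceed
  chemical tunnel radii by roughly an atomic radius; comparisons against
  construction truth use the same convention.
* Bundle walls of the synthetic structures are porous at helix scale, so
  running the grid finder on them yields wide inter-helix passages; the
  planted channel JSON is the intended tunnel source for cohort analyses.
* The per-amino-acid adherence mode aggregates over the whole cohort
  before testing monotonicity, so single-protein outliers are invisible at
  that level.
* Transcript-variant tables are matched by position only; no transcript-
  to-protein coordinate mapping is performed.
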