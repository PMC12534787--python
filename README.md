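# tunnelgrad

Pathogenicity gradients along protein tunnels.

Enzymes with buried active sites — the cytochrome P450 family is the
motivating example — reach their cofactor through tunnels: continuous
channels from the protein surface to the active-site cavity. Missense
variants near these transport routes, and especially near the cofactor
itself, are disproportionately likely to disrupt function. `tunnelgrad`
quantifies this as a monotone gradient in predicted variant pathogenicity
across three nested structural regions:

    mean(protein)  <  mean(tunnel)  <  mean(cofactor)

where the inequalities reverse for tools that score on an inverse scale
(low = pathogenic, SIFT-style).

The package is a library for Python users (plus a thin `tunnelgrad` CLI)
that covers the full analysis:

* **Structures** — read PDB files, partition heavy atoms into protein and
  one cofactor HET group (default `HEM`); hydrogens, waters, other ligands
  and extra models are dropped.
* **Tunnels** — read MOLE-style centerline JSON exports, or compute
  widest-bottleneck escape paths from the cofactor with a built-in
  voxel-grid finder (probe 5 Å, interior threshold 1.1 Å, origin radius
  5 Å, bottleneck 1.2 Å, surface cover 10 Å by default).
* **Residue sets** — tunnel-lining residues (five closest protein atoms at
  regular centerline sample points, mapped to parent residues, union over
  points and tunnels) and cofactor-proximal residues (five closest protein
  atoms per cofactor atom, non-redundant union).
* **Scores** — per-substitution pathogenicity tables in three dialects
  (long-form variant tables, position x substitution matrices,
  transcript-variant tables), averaged per residue over all available
  non-synonymous substitutions.
* **Region statistics** — per-protein region means, amino-acid frequency
  profiles, per-amino-acid group averages, score-frequency histograms,
  adherence rates to the monotone pattern, and paired t-tests
  (t = mean(d)/(sd(d)/sqrt(n)), n-1 degrees of freedom) with the tier
  convention \*\*P<.05, \*\*\*P<.005, \*\*\*\*P<.0005.
* **Synthetic data** — fully self-contained test cohorts: helix-bundle
  shells with a buried pseudo-cofactor, a planted channel of known radius,
  and score tables with a planted gradient
  `b + g*exp(-d/lambda) + Normal(0, sigma)` toward the cofactor.

## Worked example

`examples/05_region_statistics.py` runs the whole analysis on a 10-protein
synthetic cohort with the default planted gradient (g=0.2, lambda=12 Å,
sigma=0.05):

```
protein : mean score 0.330 (+/- 0.002 across proteins)
tunnel  : mean score 0.372 (+/- 0.013 across proteins)
cofactor: mean score 0.400 (+/- 0.012 across proteins)
adherence: 100.0% (10/10 proteins show protein < tunnel < cofactor)
protein vs tunnel: t = 9.42, p = 5.87e-06, tier '****'
tunnel vs cofactor: t = 6.05, p = 1.90e-04, tier '****'
```

The region means rise toward the cofactor by construction; every protein
adheres to the monotone pattern, and both paired comparisons are
significant at the strictest tier. The other example scripts demonstrate
cohort materialisation on disk, the tunnel finder, residue-set
construction with provenance, and score aggregation.

A full run from the shell:

```sh
tunnelgrad make-cohort --out cohort --n-proteins 10 --seed 42
tunnelgrad run cohort/manifest.yaml --out results
```

which writes `results/report.json` plus TSV tables of region means,
residue sets, and per-residue score means.

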