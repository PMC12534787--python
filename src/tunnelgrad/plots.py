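"""Optional figure helpers mirroring the standard presentation of the
analysis: amino-acid frequency bars per region, the amino acid x region
group-mean heatmap, and region mean bars with significance stars."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .residue_sets import REGIONS


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_frequency_profiles(profiles: dict[str, pd.Series], path) -> None:
    """Grouped bars: relative amino-acid frequency (%) per region."""
    plt = _mpl()
    regions = [r for r in REGIONS if r in profiles]
    aas = list(profiles[regions[0]].index)
    x = np.arange(len(aas))
    width = 0.8 / len(regions)
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, region in enumerate(regions):
        ax.bar(x + i * width, profiles[region].values, width, label=region)
    ax.set_xticks(x + width)
    ax.set_xticklabels(aas)
    ax.set_ylabel("frequency (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_group_means(group_means: pd.DataFrame, path) -> None:
    """Heatmap of per-amino-acid mean pathogenicity per region."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 8))
    data = group_means[list(REGIONS)]
    im = ax.imshow(data.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(data.columns)))
    ax.set_xticklabels(data.columns, rotation=45)
    ax.set_yticks(range(len(data.index)))
    ax.set_yticklabels(data.index)
    fig.colorbar(im, ax=ax, label="mean score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_region_means(summaries, tests, path) -> None:
    """Bar chart of cohort-level region means with 95% CIs and star tiers."""
    plt = _mpl()
    by_region: dict[str, list[float]] = {r: [] for r in REGIONS}
    for s in summaries:
        if s.mean_score is not None:
            by_region[s.region].append(s.mean_score)
    means = [np.mean(by_region[r]) for r in REGIONS]
    cis = [1.96 * np.std(by_region[r], ddof=1) / np.sqrt(len(by_region[r]))
           for r in REGIONS]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(REGIONS, means, yerr=cis, capsize=4)
    top = max(m + c for m, c in zip(means, cis))
    for t in tests:
        i = REGIONS.index(t.comparison[0])
        j = REGIONS.index(t.comparison[1])
        y = top + 0.03 * (j + 1) * max(top, 0.1)
        ax.plot([i, j], [y, y], color="k", lw=1)
        ax.text((i + j) / 2, y, t.stars, ha="center", va="bottom")
    ax.set_ylabel("mean pathogenicity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
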