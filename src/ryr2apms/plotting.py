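"""Optional scatter plots of enrichment ratios and phospho quadrants.

Matplotlib is imported lazily so the rest of the package has no hard
plotting dependency.  Both plots use log-scaled axes with dotted guide
lines at the decision thresholds.
"""

from __future__ import annotations

from typing import Sequence

from .enrichment_scoring import DEFAULT_CUTOFF, EnrichmentRecord
from .phospho_differential import PhosphoRecord

_CATEGORY_COLORS = {
    "bait": "tab:red",
    "both_enriched": "tab:blue",
    "igg_only": "gold",
    "beads_only": "gold",
    "not_enriched": "0.6",
}


def plot_enrichment(records: Sequence[EnrichmentRecord], path,
                    cutoff: float = DEFAULT_CUTOFF) -> None:
    """Dual-control ratio scatter (bait/IgG vs bait/beads) for one experiment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rec in records:
        ax.scatter(rec.ratio_igg, rec.ratio_beads,
                   c=_CATEGORY_COLORS.get(rec.category, "0.6"), s=18,
                   edgecolors="none")
    ax.axvline(cutoff, ls=":", c="k", lw=1)
    ax.axhline(cutoff, ls=":", c="k", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("anti-bait / IgG (LFQ ratio)")
    ax.set_ylabel("anti-bait / beads (LFQ ratio)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_quadrants(records: Sequence[PhosphoRecord], path,
                   threshold: float = 1.0) -> None:
    """S2814A/WT vs S2814D/WT normalized-PSM ratio scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [r.ratio_a_wt for r in records if r.ratio_a_wt and r.ratio_d_wt]
    ys = [r.ratio_d_wt for r in records if r.ratio_a_wt and r.ratio_d_wt]
    ax.scatter(xs, ys, c="0.3", s=18, edgecolors="none")
    ax.axvline(threshold, ls=":", c="k", lw=1)
    ax.axhline(threshold, ls=":", c="k", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("S2814A / WT (normalized PSM)")
    ax.set_ylabel("S2814D / WT (normalized PSM)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
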