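"""Optional simple plots for the dilution and presence/absence tables."""

from __future__ import annotations

import numpy as np

from .concord import DilutionRatioSet, PresenceAbsenceTable

__all__ = ["plot_dilution_histogram", "plot_presence_absence_bars"]


def plot_dilution_histogram(dilution: DilutionRatioSet, ax=None, bins=30):
    """Histogram of log2 focal/composite RPKM ratios; the dashed line marks
    ratio 1 (equal expression in both extractions)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.log2(dilution.ratios.to_numpy()), bins=bins, color="#4878a8")
    ax.axvline(0.0, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("log2(focal RPKM / composite RPKM)")
    ax.set_ylabel("genes")
    ax.set_title(f"{dilution.focal} vs {dilution.composite}")
    return ax


def plot_presence_absence_bars(table: PresenceAbsenceTable, ax=None):
    """Side-by-side bars of (+focal,-composite) and (-focal,+composite) genes
    per expression bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = [str(i) for i in table.bins_focal_only.index]
    x = np.arange(len(labels))
    ax.bar(x - 0.2, table.bins_focal_only.to_numpy(), width=0.4, label="+focal / -composite")
    ax.bar(x + 0.2, table.bins_composite_only.to_numpy(), width=0.4, label="-focal / +composite")
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("genes")
    ax.set_xlabel("RPKM bin")
    ax.legend()
    return ax
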