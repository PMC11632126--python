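"""Minimal DVH plotting helper."""

from __future__ import annotations

from .dvh import DVHCurve


def plot_dvh(dvhs: dict[str, DVHCurve], ax=None, relative: bool = True):
    """Plot cumulative DVHs (percent volume by default). Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for name, curve in dvhs.items():
        y = curve.cum_volume_cc
        if relative and curve.total_volume_cc > 0:
            y = 100.0 * y / curve.total_volume_cc
        ax.plot(curve.dose_edges, y, label=name)
    ax.set_xlabel("Dose [Gy]")
    ax.set_ylabel("Volume [%]" if relative else "Volume [cc]")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=8, ncol=2)
    return ax
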