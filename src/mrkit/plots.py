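"""Optional scatter-with-slope plots of an instrument.

Requires matplotlib (install the ``plots`` extra); imported lazily so the
rest of the package has no plotting dependency.
"""

from __future__ import annotations

from typing import Optional

from .types import HarmonizedInstrument, MREstimate


def plot_instrument(
    instrument: HarmonizedInstrument,
    estimate: Optional[MREstimate] = None,
    path=None,
    title: Optional[str] = None,
):
    """Variant-outcome vs variant-exposure associations with error bars.

    Each point is one variant's (beta_x, beta_y) pair with +/- 1.96 SE
    whiskers; when ``estimate`` is given its slope through the origin is
    drawn, visualizing the fitted causal effect. Returns the matplotlib
    Axes; saves to ``path`` when provided.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        instrument.beta_x,
        instrument.beta_y,
        xerr=1.96 * instrument.se_x,
        yerr=1.96 * instrument.se_y,
        fmt="o",
        color="tab:blue",
        ecolor="lightblue",
        elinewidth=1,
        capsize=2,
    )
    if estimate is not None:
        xs = [min(0.0, instrument.beta_x.min()), max(0.0, instrument.beta_x.max())]
        ax.plot(xs, [estimate.estimate * x for x in xs], color="navy",
                label=f"{estimate.method}: {estimate.estimate:.3f}")
        ax.legend(frameon=False)
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.axvline(0.0, lw=0.5, color="grey")
    ax.set_xlabel("variant-exposure association (beta_x)")
    ax.set_ylabel("variant-outcome association (beta_y)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
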