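"""Basic profile figures (requires the optional matplotlib dependency)."""

from __future__ import annotations

from .engine import SimulationResult


def plot_profiles(result: SimulationResult, compartments=("plasma", "kidney"),
                  logscale: bool = True, ax=None):
    """Concentration-time curves for selected compartments; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name in compartments:
        ax.plot(result.times, result.conc[name], label=name)
    if logscale:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend(frameon=False)
    return ax
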