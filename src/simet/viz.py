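"""Plotting helpers: PDD curves and scan paths."""

from __future__ import annotations

from .pdd import EnergyLibrary, R90Table
from .sequencer import EnergyGroup, ScanPlan


def plot_library(library: EnergyLibrary, table: R90Table | None = None, ax=None):
    """Plot the library's PDD curves (and optionally composited entries)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for e in library:
        ax.plot(e.curve.depths, e.curve.dose, label=f"E{e.energy_id} (R90 {e.r90:g} mm)")
    if table is not None:
        for key, spec in sorted(table.specs.items()):
            if spec.kind == "composited":
                c = table.realize(key)
                ax.plot(c.depths, c.dose, lw=0.6, alpha=0.4, color="gray")
    ax.axhline(90, ls=":", color="k", lw=0.8)
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel("dose (%)")
    ax.legend()
    return ax


def plot_scan_path(group: EnergyGroup, ax=None, **kwargs):
    """Draw a group's scan path in delivery order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = group.positions()
    ax.plot(pos[:, 0], pos[:, 1], "o-", ms=3, **kwargs)
    ax.plot(*pos[0], "s", color="green")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"E{group.energy_id}, N = {len(group)}")
    return ax


def plot_plan(plan: ScanPlan, axes=None):
    """One scan-path panel per energy group."""
    import matplotlib.pyplot as plt

    n = plan.n_energies
    if axes is None:
        _, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
        axes = axes[0]
    for ax, group in zip(axes, plan.groups):
        plot_scan_path(group, ax=ax)
    return axes
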