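"""Convenience plots for pipeline outputs (matplotlib, Agg-safe).

The pipeline's deliverables are the tables; these helpers render them for
quick inspection.
"""

from __future__ import annotations

import numpy as np

from .staging import STAGE_NAMES

__all__ = ["plot_heatmap", "plot_regional_radar"]


def plot_heatmap(table, ax=None, title=None):
    """Render a stage heatmap table (genes x regions, values in [0, 1])."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * table.shape[1] + 2, 0.3 * table.shape[0] + 1.5))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="inferno", vmin=0, vmax=1)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="row-normalized importance")
    if title:
        ax.set_title(title)
    return ax


def plot_regional_radar(profiles, ax=None):
    """Radar chart of stage-level regional importance profiles.

    ``profiles`` maps stage -> StageRegionProfile (as built by the
    pipeline); all profiles must share the same region order.
    """
    import matplotlib.pyplot as plt

    first = next(iter(profiles.values()))
    regions = list(first.profile.index)
    angles = np.linspace(0, 2 * np.pi, len(regions), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for stage, prof in sorted(profiles.items()):
        vals = prof.profile.reindex(regions).to_numpy()
        closed = np.concatenate([vals, vals[:1]])
        ang = np.concatenate([angles, angles[:1]])
        ax.plot(ang, closed, label=STAGE_NAMES.get(stage, stage))
        ax.fill(ang, closed, alpha=0.15)
    ax.set_xticks(angles, regions, fontsize=8)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    return ax


def radar_polygon_area(profile) -> float:
    """Area of the radar polygon spanned by one stage's profile."""
    vals = np.asarray(profile.profile, dtype=float)
    n = len(vals)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = vals * np.cos(angles)
    y = vals * np.sin(angles)
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
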