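"""Simple polar bull's-eye export for per-segment values."""

from __future__ import annotations

import numpy as np

# (ring index, start azimuth deg, extent deg) per AHA segment
_SEG_GEOMETRY = {
    **{s: (3, (s - 1) * 60.0, 60.0) for s in range(1, 7)},
    **{s: (2, (s - 7) * 60.0, 60.0) for s in range(7, 13)},
    **{s: (1, (s - 13) * 90.0, 90.0) for s in range(13, 17)},
    17: (0, 0.0, 360.0),
}


def bullseye_plot(segment_values: dict[int, float], ax=None, cmap="RdBu_r", vmin=None, vmax=None):
    """Draw a 17-segment bull's-eye of per-segment values.

    ``segment_values`` maps AHA segment number (1–17) to a scalar; missing
    segments are left blank.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vals = [v for v in segment_values.values() if np.isfinite(v)]
    if vmin is None:
        vmin = min(vals) if vals else 0.0
    if vmax is None:
        vmax = max(vals) if vals else 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
    for seg, (ring, start, extent) in _SEG_GEOMETRY.items():
        if seg not in segment_values or not np.isfinite(segment_values[seg]):
            continue
        theta = np.radians(np.linspace(start, start + extent, 32))
        r0, r1 = ring, ring + 1
        ax.fill_between(theta, r0, r1, color=mapper.to_rgba(segment_values[seg]))
        ax.annotate(
            f"{segment_values[seg]:.3g}",
            (np.radians(start + extent / 2), (r0 + r1) / 2),
            ha="center",
            va="center",
            fontsize=7,
        )
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.set_ylim(0, 4)
    ax.figure.colorbar(mapper, ax=ax, shrink=0.8)
    return ax
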