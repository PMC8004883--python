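"""Goodness-of-fit visualization: the 4-parameter SSR chart.

Four fitted parameters plus the residual level are packed into one static 3D
scatter: x = incident angle, y = Au thickness, z = log10 SSR, marker color =
probe refractive index, marker size = probe thickness.  A funnel-shaped
contour of the cloud indicates a well-localized error minimum; several pockets
at similar depth reveal equivalent models.

Plots are never the testable surface — every plot ships with a companion CSV
(the trace table) so its content can be asserted without image comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import write_trace

__all__ = ["VisualizationSpec", "plot_trace"]

LOG10_PLOT_FLOOR = -16.0  # zero SSR floored here for plotting only


@dataclass(frozen=True)
class VisualizationSpec:
    x_label: str = "incident angle (deg)"
    y_label: str = "Au thickness (nm)"
    z_label: str = "log10 SSR (rad$^2$)"
    color_label: str = "probe RI"
    size_label: str = "probe thickness (nm)"
    size_range: tuple[float, float] = (10.0, 120.0)
    cmap: str = "viridis"


def plot_trace(trace, out_path, spec: VisualizationSpec | None = None) -> Path:
    """Render the SSR chart to ``out_path`` and write the companion CSV next to it.

    Returns the companion table path (``<out_path>.csv``).
    """
    if not trace:
        raise ValueError("empty optimization trace")
    spec = spec or VisualizationSpec()
    out_path = Path(out_path)

    x = np.array([t.incident_angle for t in trace])
    y = np.array([t.au_thickness for t in trace])
    z = np.array([max(t.log10_ssr, LOG10_PLOT_FLOOR) for t in trace])
    color = np.array([t.probe_ri for t in trace])
    size_raw = np.array([t.probe_thickness for t in trace])
    lo, hi = size_raw.min(), size_raw.max()
    s_lo, s_hi = spec.size_range
    sizes = np.full_like(size_raw, 0.5 * (s_lo + s_hi)) if hi == lo else (
        s_lo + (size_raw - lo) / (hi - lo) * (s_hi - s_lo)
    )

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(x, y, z, c=color, s=sizes, cmap=spec.cmap, alpha=0.8, edgecolors="k", linewidths=0.3)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.set_zlabel(spec.z_label)
    cb = fig.colorbar(sc, ax=ax, shrink=0.6, pad=0.1)
    cb.set_label(spec.color_label)
    ax.set_title(f"SSR chart ({len(trace)} trials; size = {spec.size_label})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    companion = out_path.with_suffix(out_path.suffix + ".csv")
    write_trace(trace, companion)
    return companion
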