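"""Olfactory-acuity proxies: bulb/cerebrum ratio and its body-size context.

The olfactory ratio is the longest diameter of the olfactory bulb (any
orientation) as a percentage of the longest diameter of the cerebral
hemisphere.  Raw ratios scale with body size, so cross-taxon comparison
plots log10(ratio %) against log10(body mass g); reference regression
lines (e.g. a theropod expectation) are supplied by the user since their
coefficients are not part of this package's sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OlfactoryResult",
    "olfactory_ratio",
    "log_olfactory_point",
    "plot_olfactory_scatter",
]


@dataclass(frozen=True)
class OlfactoryResult:
    bulb_length: float  # longest olfactory-bulb diameter, mm
    cerebrum_diameter: float  # longest cerebral-hemisphere diameter, mm
    ratio_pct: float
    log_ratio: float | None = None  # log10 of the percentage
    log_body_mass: float | None = None  # log10 of body mass in g


def olfactory_ratio(bulb_length: float, cerebrum_diameter: float) -> float:
    """Olfactory bulb diameter as a percentage of cerebral hemisphere diameter."""
    if not (bulb_length > 0 and math.isfinite(bulb_length)):
        raise ValueError(f"bulb length must be positive, got {bulb_length!r}")
    if not (cerebrum_diameter > 0 and math.isfinite(cerebrum_diameter)):
        raise ValueError(
            f"cerebrum diameter must be positive, got {cerebrum_diameter!r}"
        )
    return 100.0 * bulb_length / cerebrum_diameter


def log_olfactory_point(ratio_pct: float, body_mass_g: float) -> tuple[float, float]:
    """(log10 ratio %, log10 body mass g) for plotting against reference lines."""
    if not (ratio_pct > 0 and math.isfinite(ratio_pct)):
        raise ValueError(f"ratio must be positive, got {ratio_pct!r}")
    if not (body_mass_g > 0 and math.isfinite(body_mass_g)):
        raise ValueError(f"body mass must be positive, got {body_mass_g!r}")
    return math.log10(ratio_pct), math.log10(body_mass_g)


def plot_olfactory_scatter(
    points,
    out_path,
    reference_line: tuple[float, float] | None = None,
    labels=None,
):
    """Scatter log10(olfactory ratio %) against log10(body mass g).

    Parameters
    ----------
    points : sequence of (log_body_mass, log_ratio) pairs
    out_path : file path for the figure (PNG/SVG by extension)
    reference_line : optional (slope, intercept)
        A user-supplied regression of log ratio on log body mass, drawn
        across the x-range of the data.
    labels : optional sequence of point labels (same length as points)
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(xs, ys, color="tab:blue", zorder=3)
    if labels is not None:
        for x, y, lab in zip(xs, ys, labels):
            ax.annotate(lab, (x, y), fontsize=7, xytext=(3, 3),
                        textcoords="offset points")
    if reference_line is not None:
        slope, intercept = reference_line
        lo, hi = min(xs), max(xs)
        pad = 0.05 * (hi - lo or 1.0)
        grid = [lo - pad, hi + pad]
        ax.plot(grid, [slope * g + intercept for g in grid],
                color="tab:grey", linestyle="--", label="reference")
        ax.legend()
    ax.set_xlabel("log10 body mass (g)")
    ax.set_ylabel("log10 olfactory ratio (%)")
    fig.tight_layout()
    fig.savefig(str(out_path))
    plt.close(fig)
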