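"""Ternary placement in the economy/flexibility/robustness persistence triangle.

Systems are scored on three non-negative axes — matter-energy budget
(economy), count of flexibility mechanisms, count of robustness mechanisms —
and placed in barycentric coordinates on a ternary plot.  The placement is a
qualitative visualization device: scores are user inputs or simulation
summaries, never inferred from molecular data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


class TriangleError(ValueError):
    pass


@dataclass(frozen=True)
class PersistenceScores:
    economy: float
    flexibility: float
    robustness: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.economy, self.flexibility, self.robustness) < 0:
            raise TriangleError("scores must be non-negative")


@dataclass(frozen=True)
class TernaryPoint:
    """Barycentric (e, f, r) coordinates, each >= 0 and summing to 1."""

    e: float
    f: float
    r: float
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isclose(self.e + self.f + self.r, 1.0, abs_tol=1e-9):
            raise TriangleError("barycentric coordinates must sum to 1")
        if min(self.e, self.f, self.r) < 0:
            raise TriangleError("barycentric coordinates must be >= 0")

    def to_cartesian(self) -> tuple[float, float]:
        """Map to the unit triangle: economy at (0,0), flexibility at (1,0),
        robustness at the apex (0.5, sqrt(3)/2)."""
        return (self.f + 0.5 * self.r, (math.sqrt(3) / 2) * self.r)


def to_ternary(scores: PersistenceScores) -> TernaryPoint:
    """Normalize raw scores to barycentric coordinates (scale-invariant)."""
    total = scores.economy + scores.flexibility + scores.robustness
    if total <= 0:
        raise TriangleError("all-zero scores cannot be placed")
    return TernaryPoint(e=scores.economy / total,
                        f=scores.flexibility / total,
                        r=scores.robustness / total,
                        label=scores.label)


def render_ternary(points: Sequence[TernaryPoint], out_path: str,
                   title: str = "triangle of persistence") -> None:
    """Deterministic matplotlib ternary plot with labeled vertices."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5.5))
    apex = (0.5, math.sqrt(3) / 2)
    tri_x = [0, 1, apex[0], 0]
    tri_y = [0, 0, apex[1], 0]
    ax.plot(tri_x, tri_y, color="black", lw=1.2)
    ax.text(-0.03, -0.05, "Economy", ha="right", va="top")
    ax.text(1.03, -0.05, "Flexibility", ha="left", va="top")
    ax.text(apex[0], apex[1] + 0.04, "Robustness", ha="center", va="bottom")
    for p in points:
        x, y = p.to_cartesian()
        ax.plot([x], [y], marker="o", ms=8, color="#386cb0")
        if p.label:
            ax.annotate(p.label, (x, y), textcoords="offset points",
                        xytext=(6, 6), fontsize=9)
    ax.set_title(title)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out_path, dpi=120, metadata=_strip_metadata(out_path))
    plt.close(fig)


def _strip_metadata(path: str) -> dict:
    # drop timestamps so repeated renders are byte-comparable
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
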