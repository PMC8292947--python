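"""Place systems in the economy/flexibility/robustness persistence triangle.

Scores are qualitative budgets/mechanism counts; each system is normalized to
barycentric coordinates and drawn in the ternary trade-off space.
"""

from pathlib import Path

from molvocab import PersistenceScores, to_ternary
from molvocab.triangle import render_ternary

systems = [
    PersistenceScores(economy=5, flexibility=1, robustness=2, label="archaea"),
    PersistenceScores(economy=4, flexibility=2.5, robustness=1.5,
                      label="bacteria"),
    PersistenceScores(economy=1.5, flexibility=5, robustness=2.5,
                      label="eukarya"),
]

points = [to_ternary(s) for s in systems]
for s, p in zip(systems, points):
    print(f"{s.label:>8}: (e, f, r) = ({p.e:.2f}, {p.f:.2f}, {p.r:.2f})")
print("  -> microbial systems gravitate toward the economy vertex; "
      "eukarya toward flexibility.")

Path("scratch").mkdir(exist_ok=True)
render_ternary(points, "scratch/triangle.png")
print("wrote scratch/triangle.png")
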