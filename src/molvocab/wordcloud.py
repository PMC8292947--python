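"""Causal word clouds of GO-term lexical units.

GO term names are tokenized into lexical units — a head (final word), an
optional sub-head (the word left of the head) and an optional modifier chain
(all remaining left words, joined in order; hyphenated words are single
tokens).  Each unit's *dominance* is the age of the oldest term that contains
it, which becomes its x-coordinate on the evolutionary timeline; the
*precedence* of units within a term's word string becomes the y-axis: the head
sits on its term's anchor row and modifiers stack above.  Units are sized by
frequency of use, colored by the Venn taxonomic group of their oldest term,
and repeated units are drawn in outline fonts.  The layout is deterministic
and collision-free by construction, and renders to byte-stable SVG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

class CloudError(ValueError):
    pass


#: fixed 7-color palette per Venn taxonomic group (reproducible legends)
GROUP_COLORS = {
    "ABE": "#c8a400",
    "AB": "#7570b3",
    "AE": "#66a61e",
    "BE": "#1b9e77",
    "A": "#d95f02",
    "B": "#386cb0",
    "E": "#e7298a",
}


@dataclass(frozen=True)
class Tokenization:
    """Lexical units of one term name, in head-final order."""

    term_id: str
    head: str
    sub_head: str | None = None
    modifier_chain: str | None = None

    @property
    def units(self) -> list[str]:
        """Units in placement order: head, then sub-head, then chain."""
        out = [self.head]
        if self.sub_head is not None:
            out.append(self.sub_head)
        if self.modifier_chain is not None:
            out.append(self.modifier_chain)
        return out

    def reconstruct(self) -> str:
        parts = [p for p in (self.modifier_chain, self.sub_head, self.head)
                 if p is not None]
        return " ".join(parts)


def tokenize(name: str, term_id: str = "") -> Tokenization:
    """Split a term name into head / sub-head / modifier-chain units.

    The last space-separated word is the head, the second-to-last the
    sub-head, and any remaining left words are joined (preserving order) into
    a single modifier chain.  Hyphenated words count as one token.
    """
    if not name or not name.strip():
        raise CloudError("empty term name")
    words = name.split()
    head = words[-1]
    sub = words[-2] if len(words) >= 2 else None
    chain = " ".join(words[:-2]) if len(words) >= 3 else None
    return Tokenization(term_id=term_id, head=head, sub_head=sub,
                        modifier_chain=chain)


@dataclass
class TermRecord:
    term_id: str
    name: str
    age: float
    group: str = "ABE"


def _check_terms(terms: Sequence[TermRecord]) -> None:
    seen: dict[str, float] = {}
    for t in terms:
        if not 0.0 <= t.age <= 1.0:
            raise CloudError(f"term {t.term_id}: age {t.age} outside [0,1]")
        if t.name in seen and seen[t.name] != t.age:
            raise CloudError(f"duplicate term name {t.name!r} with conflicting ages")
        seen[t.name] = t.age


def dominance_ages(terms: Sequence[TermRecord]) -> dict[str, float]:
    """Dominance of each lexical unit = minimum age over containing terms."""
    _check_terms(terms)
    dom: dict[str, float] = {}
    for t in terms:
        for unit in tokenize(t.name, t.term_id).units:
            if unit not in dom or t.age < dom[unit]:
                dom[unit] = t.age
    return dom


def unit_frequencies(terms: Sequence[TermRecord]) -> Counter:
    """How many terms use each lexical unit."""
    freq: Counter = Counter()
    for t in terms:
        freq.update(set(tokenize(t.name, t.term_id).units))
    return freq


def frequency_sizes(counts: Mapping[str, int], min_size: float = 10.0,
                    max_size: float = 30.0) -> dict[str, float]:
    """Linear map from unit frequency to font size.

    All-equal counts map to the midpoint of the size range.
    """
    if not counts:
        raise CloudError("empty unit counts")
    if not max_size > min_size > 0:
        raise CloudError("require max_size > min_size > 0")
    lo, hi = min(counts.values()), max(counts.values())
    if hi == lo:
        mid = (min_size + max_size) / 2.0
        return {u: mid for u in counts}
    scale = (max_size - min_size) / (hi - lo)
    return {u: min_size + (c - lo) * scale for u, c in counts.items()}


@dataclass
class CloudStyle:
    min_font: float = 10.0
    max_font: float = 30.0
    char_width: float = 0.6   # box width = char_width * font * len(unit)
    line_height: float = 1.2  # box height = line_height * font
    canvas_width: float = 1000.0
    margin: float = 60.0

    @property
    def row_height(self) -> float:
        return self.line_height * self.max_font

    def x_canvas(self, age: float) -> float:
        return self.margin + age * (self.canvas_width - 2 * self.margin)

    def box(self, unit: str, age: float, size: float) -> tuple[float, float]:
        """Half-open x-interval of the unit's bounding box in canvas units."""
        x0 = self.x_canvas(age)
        return (x0, x0 + self.char_width * size * len(unit))


@dataclass
class Placement:
    unit: str
    x: float          # dominance age in [0, 1]
    y: int            # row index (precedence axis)
    size: float
    color: str
    group: str
    outline: bool
    bbox: tuple[float, float]  # canvas x-interval


@dataclass
class CloudLayout:
    placements: list[Placement]
    style: CloudStyle
    legend: dict[str, str] = field(default_factory=lambda: dict(GROUP_COLORS))

    @property
    def n_rows(self) -> int:
        return 1 + max((p.y for p in self.placements), default=0)


def _boxes_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def layout(terms: Sequence[TermRecord],
           style: CloudStyle | None = None) -> CloudLayout:
    """Place every lexical unit on the dominance x precedence plane.

    Terms are processed oldest-first (age ties broken by term id).  Each unit
    not yet placed goes at x = its dominance age, starting on the row of its
    term's anchor — the unit of the same term placed just before it, or the
    base row for a term's first unit.  On a bounding-box collision with any
    unit already on that row, the unit moves up one row at a time until free
    ("placed above its associated word").  Already-placed units never move;
    a unit required again later is simply flagged as repeated (outline font).
    """
    style = style or CloudStyle()
    _check_terms(terms)
    ordered = sorted(terms, key=lambda t: (t.age, t.term_id))
    dom = dominance_ages(terms)
    sizes = frequency_sizes(unit_frequencies(terms), style.min_font, style.max_font)
    oldest: dict[str, TermRecord] = {}
    for t in ordered:
        for u in tokenize(t.name, t.term_id).units:
            oldest.setdefault(u, t)  # first occurrence is oldest (sorted order)

    placed: dict[str, Placement] = {}
    rows: dict[int, list[tuple[float, float]]] = {}
    out: list[Placement] = []
    for t in ordered:
        tok = tokenize(t.name, t.term_id)
        anchor_row: int | None = None
        for unit in tok.units:
            if unit in placed:
                placed[unit].outline = True
                anchor_row = placed[unit].y
                continue
            x_age = dom[unit]
            size = sizes[unit]
            bbox = style.box(unit, x_age, size)
            row = anchor_row if anchor_row is not None else 0
            while any(_boxes_overlap(bbox, b) for b in rows.get(row, [])):
                row += 1
            group = oldest[unit].group
            p = Placement(unit=unit, x=x_age, y=row, size=size,
                          color=GROUP_COLORS.get(group, "#444444"),
                          group=group, outline=False, bbox=bbox)
            placed[unit] = p
            rows.setdefault(row, []).append(bbox)
            out.append(p)
            anchor_row = row
    return CloudLayout(placements=out, style=style)


def combine_layouts(layouts: Sequence[CloudLayout]) -> CloudLayout:
    """Stack per-Venn-group layouts into one cloud.

    Each subsequent layout's rows are shifted above the rows already occupied,
    so the union of placements is preserved with no cross-group box overlap.
    """
    if not layouts:
        raise CloudError("no layouts to combine")
    style = layouts[0].style
    merged: list[Placement] = []
    offset = 0
    for lay in layouts:
        for p in lay.placements:
            merged.append(Placement(unit=p.unit, x=p.x, y=p.y + offset,
                                    size=p.size, color=p.color, group=p.group,
                                    outline=p.outline, bbox=p.bbox))
        offset += lay.n_rows
    return CloudLayout(placements=merged, style=style)


def render_svg(cloud: CloudLayout, title: str = "causal word cloud") -> str:
    """Deterministic SVG: one text element per placement plus an age axis.

    Outlined (repeated) units are stroked with unfilled glyphs; the x-axis is
    annotated as relative age from 0 (origin) to 1 (present).
    """
    st = cloud.style
    n_rows = max(cloud.n_rows, 1)
    axis_h = 40.0
    height = st.margin + n_rows * st.row_height + axis_h
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{st.canvas_width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {st.canvas_width:.0f} {height:.0f}">',
        f'<title>{title}</title>',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    base_y = height - axis_h
    # axis: relative age 0 -> 1
    lines.append(
        f'<line x1="{st.x_canvas(0):.1f}" y1="{base_y + 8:.1f}" '
        f'x2="{st.x_canvas(1):.1f}" y2="{base_y + 8:.1f}" stroke="black"/>')
    for tick in (0.0, 0.25, 0.5, 0.75, 1.0):
        xc = st.x_canvas(tick)
        lines.append(f'<line x1="{xc:.1f}" y1="{base_y + 8:.1f}" '
                     f'x2="{xc:.1f}" y2="{base_y + 13:.1f}" stroke="black"/>')
        lines.append(f'<text x="{xc:.1f}" y="{base_y + 26:.1f}" font-size="11" '
                     f'text-anchor="middle">{tick:g}</text>')
    lines.append(f'<text x="{st.canvas_width / 2:.1f}" y="{base_y + 39:.1f}" '
                 'font-size="12" text-anchor="middle">'
                 'relative age (0 = origin, 1 = present)</text>')
    for p in sorted(cloud.placements, key=lambda p: (p.y, p.bbox[0], p.unit)):
        xc = p.bbox[0]
        yc = base_y - p.y * st.row_height - 0.25 * st.row_height
        attrs = (f'x="{xc:.2f}" y="{yc:.2f}" font-size="{p.size:.2f}" '
                 f'font-family="sans-serif"')
        if p.outline:
            attrs += f' fill="none" stroke="{p.color}" stroke-width="0.8"'
        else:
            attrs += f' fill="{p.color}"'
        lines.append(f'<text {attrs}>{_xml_escape(p.unit)}</text>')
    lines.append('</svg>')
    return "\n".join(lines) + "\n"


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def placement_table(cloud: CloudLayout) -> str:
    """TSV of placements (unit, x, y, size, group, outline) for testing."""
    rows = ["unit\tx\ty\tsize\tgroup\toutline"]
    for p in sorted(cloud.placements, key=lambda p: (p.y, p.x, p.unit)):
        rows.append(f"{p.unit}\t{p.x:.6f}\t{p.y}\t{p.size:.3f}\t{p.group}"
                    f"\t{int(p.outline)}")
    return "\n".join(rows) + "\n"
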