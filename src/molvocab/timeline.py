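"""Evolutionary timelines of traits and Gene Ontology terms.

Relative ages on a 0 (origin) to 1 (present) scale are derived from rooted
trees as normalized root-to-node distances, optionally mapped to geological
time (Gy before present) by a linear molecular clock.  GO terms are organized
into levels over the ``is_a`` hierarchy, terminal (leaf) terms extracted per
namespace, and the distribution index *f* tracked along the timeline to expose
the "losing" (vertical dilution/loss) and "expansive" (late horizontal spread)
trends, including first-complete-loss ages and the age ordering of Venn
taxonomic groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .census import OccurrenceMatrix, VennPartition, f_index

NAMESPACES = ("mf", "bp", "cc")
#: long-form Gene Ontology namespace names accepted on input
NAMESPACE_ALIASES = {
    "molecular_function": "mf", "biological_process": "bp",
    "cellular_component": "cc", "mf": "mf", "bp": "bp", "cc": "cc",
}


class TimelineError(ValueError):
    pass


# --------------------------------------------------------------------------
# ontology graph
# --------------------------------------------------------------------------

@dataclass
class OntologyGraph:
    """GO-style DAG: nodes carry name/namespace, edges child -> parent typed
    ``is_a``, ``part_of`` or ``regulates``."""

    graph: nx.MultiDiGraph

    def __post_init__(self) -> None:
        isa = self.isa_subgraph()
        if not nx.is_directed_acyclic_graph(isa):
            raise TimelineError("is_a relation is cyclic")

    def isa_subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes(data=True))
        for u, v, key in self.graph.edges(keys=True):
            if key == "is_a":
                g.add_edge(u, v)
        return g

    def terms(self, namespace: str | None = None) -> list[str]:
        ns = NAMESPACE_ALIASES.get(namespace, namespace) if namespace else None
        return [t for t, d in self.graph.nodes(data=True)
                if ns is None or NAMESPACE_ALIASES.get(d.get("namespace")) == ns]

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)


def build_ontology(terms: Iterable[tuple[str, str, str]],
                   edges: Iterable[tuple[str, str, str]]) -> OntologyGraph:
    """Assemble an OntologyGraph from (id, name, namespace) and
    (child, parent, type) tuples."""
    g = nx.MultiDiGraph()
    for tid, name, ns in terms:
        if ns not in NAMESPACE_ALIASES:
            raise TimelineError(f"term {tid}: unknown namespace {ns!r}")
        g.add_node(tid, name=name, namespace=NAMESPACE_ALIASES[ns])
    for child, parent, etype in edges:
        if etype not in ("is_a", "part_of", "regulates"):
            raise TimelineError(f"unknown edge type {etype!r}")
        for t in (child, parent):
            if t not in g:
                raise TimelineError(f"edge endpoint {t} not a declared term")
        g.add_edge(child, parent, key=etype)
    return OntologyGraph(g)


def terminal_terms(ontology: OntologyGraph, namespace: str) -> set[str]:
    """DAG leaves of a namespace: terms with no ``is_a`` child in it."""
    ns = NAMESPACE_ALIASES.get(namespace)
    if ns is None:
        raise TimelineError(f"unknown namespace {namespace!r}")
    members = set(ontology.terms(ns))
    if not members:
        raise TimelineError(f"namespace {namespace!r} has no terms")
    isa = ontology.isa_subgraph()
    with_child = {v for u, v in isa.edges() if u in members}
    return members - with_child


@dataclass
class LeveledOntology:
    """Term -> level assignment over the is_a hierarchy (root at level 0)."""

    levels: dict[str, int]
    excluded: list[str]
    collapse: str = "min"

    def at_level(self, level: int) -> list[str]:
        return sorted(t for t, l in self.levels.items() if l == level)


def assign_levels(ontology: OntologyGraph, namespace: str = "mf",
                  max_level: int | None = None,
                  collapse: str = "min") -> LeveledOntology:
    """Assign each term of a namespace to a single GO level.

    Levels are depths over ``is_a`` edges only, with the namespace root at
    level 0 and its direct children at level 1.  A term reachable at several
    depths is collapsed to one retained level (``collapse`` = ``"min"``
    shallowest, default, or ``"max"`` deepest).  Terms with no ``is_a`` path to
    the root — connected only through ``part_of``/``regulates`` — are excluded
    and reported.  Childless parents simply retain their own level.  With
    ``max_level`` set, deeper terms are dropped from the result.
    """
    if collapse not in ("min", "max"):
        raise TimelineError(f"collapse must be min or max, got {collapse!r}")
    ns = NAMESPACE_ALIASES.get(namespace)
    members = set(ontology.terms(ns))
    if not members:
        raise TimelineError(f"namespace {namespace!r} has no terms")
    isa = ontology.isa_subgraph().subgraph(members)
    # the root has no is_a parent; terms that are fully isolated in the is_a
    # relation (only part_of/regulates links) are not root candidates
    roots = [t for t in members
             if isa.out_degree(t) == 0 and (isa.in_degree(t) > 0 or len(members) == 1)]
    if len(roots) != 1:
        raise TimelineError(f"expected one namespace root, found {sorted(roots)}")
    root = roots[0]
    # depths along is_a, child->parent edges reversed for top-down traversal
    down = isa.reverse(copy=False)
    reachable = {root} | nx.descendants(down, root)
    depths: dict[str, int] = {}
    if collapse == "min":
        depths = dict(nx.single_source_shortest_path_length(down, root))
    else:  # longest path depth via topological DP (graph is acyclic)
        for t in nx.topological_sort(down):
            if t == root:
                depths[t] = 0
            elif t in reachable:
                depths[t] = max(depths[p] + 1 for p in down.predecessors(t)
                                if p in depths)
    excluded = sorted(members - set(depths))
    if max_level is not None:
        depths = {t: l for t, l in depths.items() if l <= max_level}
    return LeveledOntology(levels=depths, excluded=excluded, collapse=collapse)


# --------------------------------------------------------------------------
# ages
# --------------------------------------------------------------------------

@dataclass
class AgeTable:
    """Trait/term id -> relative evolutionary age nd in [0, 1]."""

    ages: dict[str, float]

    def __post_init__(self) -> None:
        bad = {t: a for t, a in self.ages.items() if not (0.0 <= a <= 1.0)}
        if bad:
            raise TimelineError(f"ages outside [0,1]: {bad}")

    def __getitem__(self, key: str) -> float:
        return self.ages[key]

    def __contains__(self, key: str) -> bool:
        return key in self.ages

    def sorted_ids(self) -> list[str]:
        """Ids ordered oldest first; exact age ties broken by id."""
        return sorted(self.ages, key=lambda t: (self.ages[t], t))


def ages_from_tree(tree, include_internal: bool = True) -> AgeTable:
    """Relative ages from a rooted tree with branch lengths.

    Each labeled node's age is its root-to-node path length divided by the
    maximum root-to-node path length, so the earliest (root-adjacent) node gets
    age 0 and the most derived node age 1.  Unlabeled nodes are skipped.
    Invariant under uniform rescaling of all branch lengths.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TimelineError("expected a dendropy Tree")
    root = tree.seed_node
    dists: dict[str, float] = {}
    maxd = 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            node._age_dist = 0.0
        else:
            edge = node.edge.length if node.edge.length is not None else 1.0
            if edge < 0:
                raise TimelineError("negative branch length")
            node._age_dist = node.parent_node._age_dist + edge
        maxd = max(maxd, node._age_dist)
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is not None and (include_internal or node.is_leaf()):
            dists[label] = node._age_dist
    if maxd <= 0:
        raise TimelineError("tree has zero total depth")
    return AgeTable({t: d / maxd for t, d in dists.items()})


@dataclass
class Clock:
    """Linear molecular clock mapping relative age to Gy before present."""

    origin_gy: float = 3.8

    def __post_init__(self) -> None:
        if self.origin_gy <= 0:
            raise TimelineError("clock origin must be positive")

    def gy(self, nd: float) -> float:
        if not 0.0 <= nd <= 1.0:
            raise TimelineError(f"relative age {nd} outside [0,1]")
        return self.origin_gy * (1.0 - nd)

    def nd(self, gy: float) -> float:
        return 1.0 - gy / self.origin_gy


def to_gy(ages: AgeTable, clock: Clock) -> dict[str, float]:
    """Map every relative age to Gy before present via the linear clock."""
    return {t: clock.gy(a) for t, a in ages.ages.items()}


# --------------------------------------------------------------------------
# timelines
# --------------------------------------------------------------------------

@dataclass
class Timeline:
    """Per-trait (age, f) series for one or more taxa."""

    taxa: list[str]
    ages: dict[str, float]
    f: dict[str, dict[str, float]]  # taxon -> trait -> f
    order: list[str] = field(default_factory=list)  # traits oldest-first

    def series(self, taxon: str) -> list[tuple[float, float]]:
        return [(self.ages[t], self.f[taxon][t]) for t in self.order]


def f_trajectory(matrix: OccurrenceMatrix, ages: AgeTable,
                 taxa: Sequence[str] = ("A", "B", "E")) -> Timeline:
    """Distribution-index trajectories along the evolutionary timeline."""
    missing = [t for t in matrix.traits if t not in ages]
    if missing:
        raise TimelineError(f"traits without ages: {missing}")
    f: dict[str, dict[str, float]] = {}
    for taxon in taxa:
        prof = f_index(matrix, taxon)
        f[taxon] = prof.as_floats()
    order = [t for t in ages.sorted_ids() if t in set(matrix.traits)]
    return Timeline(taxa=list(taxa), ages={t: ages[t] for t in order},
                    f=f, order=order)


def first_loss_age(timeline: Timeline, taxon: str) -> float | None:
    """Earliest age among traits completely lost (f = 0) in a taxon."""
    lost = [timeline.ages[t] for t in timeline.order
            if timeline.f[taxon][t] == 0.0]
    return min(lost) if lost else None


@dataclass
class GroupAgeStats:
    medians: dict[str, float | None]
    ranking: list[str]
    outliers: dict[str, list[str]]


def group_age_stats(ages: AgeTable, partition: VennPartition,
                    iqr_factor: float = 1.5) -> GroupAgeStats:
    """Median age per Venn group, oldest-first ranking, and boxplot outliers.

    Outliers follow the 1.5 x IQR boxplot convention per group.  Empty groups
    get an undefined (None) median and are omitted from the ranking.
    """
    medians: dict[str, float | None] = {}
    outliers: dict[str, list[str]] = {}
    for g in partition.groups:
        members = partition.members.get(g, [])
        missing = [t for t in members if t not in ages]
        if missing:
            raise TimelineError(f"group {g}: members without ages: {missing}")
        vals = np.array([ages[t] for t in members])
        if len(vals) == 0:
            medians[g] = None
            outliers[g] = []
            continue
        medians[g] = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        lo, hi = q1 - iqr_factor * (q3 - q1), q3 + iqr_factor * (q3 - q1)
        outliers[g] = sorted(t for t in members
                             if not lo <= ages[t] <= hi)
    ranking = sorted((g for g in partition.groups if medians[g] is not None),
                     key=lambda g: (medians[g], g))
    return GroupAgeStats(medians=medians, ranking=ranking, outliers=outliers)
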