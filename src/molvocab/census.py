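"""Occurrence-matrix censuses: distribution index *f*, Venn taxonomic groups,
and cross-census summaries.

The substrate is a traits x genomes matrix of non-negative occurrence counts
with each genome labeled by superkingdom (Archaea ``A``, Bacteria ``B``,
Eukarya ``E``, optionally viruses ``V``).  Presence/absence (count >= 1) drives
both the distribution index and the Venn partition; abundance is retained only
for the linguistic-law fits.

The distribution index ``f`` of a trait within a genome subset is the fraction
of genomes in the subset that carry the trait at least once — a popularity
measure on a 0-1 scale where ``f = 1`` means universal presence.  Traits are
classified into the seven disjoint Venn taxonomic groups (ABE, AB, AE, BE, A,
B, E) by which superkingdoms contain them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

SUPERKINGDOMS = ("A", "B", "E")
VENN_GROUPS = ("ABE", "AB", "AE", "BE", "A", "B", "E")
#: 15-group partition when viruses (V) are included.
VENN_GROUPS_V = tuple(
    "".join(c for c in "ABEV" if c in combo)
    for r in range(4, 0, -1)
    for combo in ("".join(s) for s in itertools.combinations("ABEV", r))
)


class CensusError(ValueError):
    """Raised on invalid census inputs (empty subsets, unlabeled genomes...)."""


@dataclass
class OccurrenceMatrix:
    """Traits x genomes occurrence counts plus genome superkingdom labels.

    Parameters
    ----------
    counts
        DataFrame indexed by trait id with genome ids as columns; integer
        counts >= 0.
    superkingdoms
        Mapping genome id -> label in {A, B, E, V}; must cover every genome.
    """

    counts: pd.DataFrame
    superkingdoms: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise CensusError("duplicate trait ids")
        if self.counts.columns.duplicated().any():
            raise CensusError("duplicate genome ids")
        if (self.counts.to_numpy() < 0).any():
            raise CensusError("negative occurrence counts")
        missing = [g for g in self.counts.columns if g not in self.superkingdoms]
        if missing:
            raise CensusError(f"genomes without superkingdom label: {missing}")
        bad = {g: s for g, s in self.superkingdoms.items()
               if g in self.counts.columns and s not in ("A", "B", "E", "V")}
        if bad:
            raise CensusError(f"unknown superkingdom labels: {bad}")

    @property
    def traits(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    def genomes_of(self, superkingdom: str) -> list[str]:
        return [g for g in self.counts.columns
                if self.superkingdoms[g] == superkingdom]

    def presence(self) -> pd.DataFrame:
        """Binarized matrix (count >= 1)."""
        return self.counts >= 1

    def trait_totals(self) -> pd.Series:
        """Total occurrences of each trait summed over all genomes."""
        return self.counts.sum(axis=1)


@dataclass
class DistributionProfile:
    """Per-trait distribution index f over a named genome subset.

    f values are exact rationals (``fractions.Fraction``) so that threshold
    comparisons at f = 1 or f = 0.5 are unambiguous.
    """

    subset: str
    n_genomes: int
    f: dict[str, Fraction]

    def as_floats(self) -> dict[str, float]:
        return {t: float(v) for t, v in self.f.items()}

    def median(self) -> float:
        return float(np.median([float(v) for v in self.f.values()]))


@dataclass
class VennPartition:
    """Disjoint trait groups by superkingdom membership pattern."""

    members: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    groups: tuple[str, ...] = VENN_GROUPS

    def __post_init__(self) -> None:
        if self.members and not self.counts:
            self.counts = {g: len(m) for g, m in self.members.items()}
        for g in self.groups:
            self.counts.setdefault(g, 0)

    def total(self, superkingdom: str) -> int:
        """Vocabulary size of one superkingdom = sum of its groups."""
        return sum(n for g, n in self.counts.items() if superkingdom in g)

    def union(self) -> int:
        """Number of traits present in at least one genome."""
        return sum(self.counts.values())

    def group_of(self, trait: str) -> str | None:
        for g, m in self.members.items():
            if trait in m:
                return g
        return None


def f_index(matrix: OccurrenceMatrix, subset: Sequence[str] | str) -> DistributionProfile:
    """Distribution index f = (# subset genomes carrying the trait) / |subset|.

    ``subset`` is either a superkingdom label or an explicit list of genome ids.
    """
    if isinstance(subset, str):
        name, genomes = subset, matrix.genomes_of(subset)
    else:
        name, genomes = ",".join(subset), list(subset)
    if not genomes:
        raise CensusError(f"empty genome subset {name!r}")
    unknown = [g for g in genomes if g not in matrix.counts.columns]
    if unknown:
        raise CensusError(f"genomes not in matrix: {unknown}")
    n = len(genomes)
    hits = matrix.presence()[genomes].sum(axis=1)
    f = {t: Fraction(int(h), n) for t, h in hits.items()}
    return DistributionProfile(subset=name, n_genomes=n, f=f)


def venn_partition(matrix: OccurrenceMatrix, include_viruses: bool = False) -> VennPartition:
    """Assign each trait present somewhere to its superkingdom-membership group.

    Viral genomes (label V) are excluded from the 7-group A/B/E partition by
    default; with ``include_viruses`` the 15-group A/B/E/V partition is built.
    """
    letters = ("A", "B", "E", "V") if include_viruses else SUPERKINGDOMS
    groups = VENN_GROUPS_V if include_viruses else VENN_GROUPS
    pres = matrix.presence()
    cols = {s: [g for g in matrix.genomes if matrix.superkingdoms[g] == s]
            for s in letters}
    in_sk = {s: (pres[cols[s]].any(axis=1) if cols[s] else None)
             for s in letters}
    members: dict[str, list[str]] = {g: [] for g in groups}
    for t in matrix.traits:
        combo = "".join(s for s in letters
                        if in_sk[s] is not None and bool(in_sk[s][t]))
        if combo:
            members[combo].append(t)
    return VennPartition(members=members, groups=groups)


def venn_complete(known: Mapping[str, int]) -> tuple[VennPartition, dict[str, int]]:
    """Reconstruct a full 7-group Venn partition from partial counts.

    ``known`` maps group names (``ABE``, ``AB``, ..., ``E``) or superkingdom
    totals (``total_A``, ``total_B``, ``total_E``) to counts.  Each total is the
    sum of the four groups containing that superkingdom; the unique non-negative
    integer solution is returned together with a record of which groups were
    solved versus given.

    Raises
    ------
    CensusError
        If the system is underdetermined (listing the free groups), infeasible,
        or forces a negative or non-integer count.
    """
    unknowns = list(VENN_GROUPS)
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for key, value in known.items():
        if key in VENN_GROUPS:
            row = [Fraction(1 if g == key else 0) for g in unknowns]
        elif key.startswith("total_") and key[6:] in SUPERKINGDOMS:
            sk = key[6:]
            row = [Fraction(1 if sk in g else 0) for g in unknowns]
        else:
            raise CensusError(f"unknown constraint name {key!r}")
        rows.append(row)
        rhs.append(Fraction(value))

    # exact rational Gaussian elimination
    m = [row + [b] for row, b in zip(rows, rhs)]
    n_unk = len(unknowns)
    pivot_cols: list[int] = []
    r = 0
    for c in range(n_unk):
        piv = next((i for i in range(r, len(m)) if m[i][c] != 0), None)
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        m[r] = [x / m[r][c] for x in m[r]]
        for i in range(len(m)):
            if i != r and m[i][c] != 0:
                factor = m[i][c]
                m[i] = [x - factor * y for x, y in zip(m[i], m[r])]
        pivot_cols.append(c)
        r += 1
    for i in range(r, len(m)):
        if m[i][n_unk] != 0:
            raise CensusError("inconsistent constraints (no solution)")
    free = [unknowns[c] for c in range(n_unk) if c not in pivot_cols]
    if free:
        raise CensusError(f"underdetermined system; free groups: {free}")
    solution: dict[str, int] = {}
    for row_i, c in enumerate(pivot_cols):
        val = m[row_i][n_unk]
        if val.denominator != 1:
            raise CensusError(f"non-integer count forced for {unknowns[c]}: {val}")
        if val < 0:
            raise CensusError(f"negative count forced for {unknowns[c]}: {val}")
        solution[unknowns[c]] = int(val)
    provenance = {g: ("given" if g in known else "solved") for g in VENN_GROUPS}
    part = VennPartition(members={}, counts=solution)
    # re-partition consistency: totals given as constraints must be reproduced
    for key, value in known.items():
        if key.startswith("total_") and part.total(key[6:]) != value:
            raise CensusError(f"solution violates {key}")
    return part, provenance


@dataclass
class FoldRatioSummary:
    """Mean, standard error and skewness of fold ratios across censuses."""

    ratios: list[float]
    mean: float
    se: float | None
    skewness: float | None


@dataclass
class CensusSummary:
    partitions: list[VennPartition]
    labels: list[str]
    vocabulary_folds: dict[str, FoldRatioSummary]
    specific_folds: dict[str, FoldRatioSummary]
    percent_universal: dict[str, float]

    @property
    def percent_universal_mean(self) -> float:
        return float(np.mean(list(self.percent_universal.values())))


def _summarize(ratios: list[float]) -> FoldRatioSummary:
    n = len(ratios)
    mean = float(np.mean(ratios))
    if n < 2:
        return FoldRatioSummary(ratios, mean, None, None)
    se = float(np.std(ratios, ddof=1) / math.sqrt(n))
    # adjusted Fisher-Pearson skewness needs n >= 3
    skew = float(_stats.skew(ratios, bias=False)) if n >= 3 else None
    return FoldRatioSummary(ratios, mean, se, skew)


def census_summary(partitions: Sequence[VennPartition],
                   labels: Sequence[str] | None = None,
                   pairs: Iterable[tuple[str, str]] = (("E", "A"), ("B", "E"))) -> CensusSummary:
    """Cross-census fold ratios and universal-core percentages.

    For each (numerator, denominator) superkingdom pair, reports the fold ratio
    of total vocabularies and of superkingdom-specific groups in each census,
    summarized by mean, SE = sd/sqrt(n), and adjusted Fisher-Pearson skewness
    (flagged ``None`` rather than zero when a single census makes them
    undefined).  Percent-universal is the ABE share of each census's union.
    """
    if not partitions:
        raise CensusError("at least one partition required")
    labels = list(labels) if labels is not None else [f"census{i}" for i in range(len(partitions))]
    vocab: dict[str, FoldRatioSummary] = {}
    specific: dict[str, FoldRatioSummary] = {}
    for num, den in pairs:
        key = f"{num}/{den}"
        vocab[key] = _summarize([p.total(num) / p.total(den) for p in partitions])
        specific[key] = _summarize([p.counts[num] / p.counts[den] for p in partitions
                                    if p.counts[den] > 0])
    pct = {lab: 100.0 * p.counts["ABE"] / p.union()
           for lab, p in zip(labels, partitions) if p.union() > 0}
    return CensusSummary(list(partitions), labels, vocab, specific, pct)


_COMPARATORS = {
    "==": lambda f, v: f == v,
    ">": lambda f, v: f > v,
    ">=": lambda f, v: f >= v,
    "<": lambda f, v: f < v,
    "<=": lambda f, v: f <= v,
}


def threshold_counts(profile: DistributionProfile,
                     thresholds: Iterable[tuple[str, float]]) -> dict[str, int]:
    """Count traits whose exact rational f satisfies each (comparator, value).

    Comparators are strict where the threshold statements are strict (e.g.
    "present in > 50% of proteomes" excludes f = 0.5 exactly).
    """
    out: dict[str, int] = {}
    for comp, value in thresholds:
        if comp not in _COMPARATORS:
            raise CensusError(f"unknown comparator {comp!r}")
        frac = Fraction(value).limit_denominator(10**9)
        out[f"f {comp} {value}"] = sum(
            1 for f in profile.f.values() if _COMPARATORS[comp](f, frac))
    return out
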