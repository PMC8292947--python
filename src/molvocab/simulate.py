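"""Synthetic-data generators for the vocabulary analyses.

Every downstream stage — law fitting, censuses, timelines, word clouds — is
exercised on data produced here, so the generators emulate the statistical
structure the analyses assume:

* Zipfian occurrence spectra (exact discrete power-law draws);
* multi-regime sublinear Heaps growth via a two-probability kernel/novelty
  stream (Yule/Simon-style frequency-proportional reuse);
* Menzerath-Altmann-scaled domain lengths with lognormal noise;
* presence/absence occurrence matrices shaped by vertical inheritance with
  per-step loss (the "losing" trend) and late horizontal transfer (the
  "expansive" trend) on fixed bifurcating lineage trees per superkingdom;
* GO-style term tables with head-final names for word-cloud fixtures.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import OccurrenceMatrix
from .laws import sample_zipf
from .timeline import AgeTable
from .wordcloud import TermRecord, tokenize


class SimulationError(ValueError):
    pass


@dataclass
class MAParams:
    """Menzerath-Altmann generator settings: z_k = A * k**b * lognormal noise."""

    A: float = 200.0   # residues, mean single-domain length
    b: float = -0.2
    sigma: float = 0.05  # log-scale noise
    kmax: int = 10
    n_per_k: int = 20

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise SimulationError("A must be positive")
        if self.sigma < 0:
            raise SimulationError("sigma must be >= 0")
        if self.kmax < 2:
            raise SimulationError("kmax must be >= 2")


@dataclass
class EvoParams:
    """Birth/loss/transfer settings for the vocabulary-evolution simulation.

    ``loss`` maps superkingdom -> per-lineage probability of losing a present
    trait per time step; ``hgt_rate`` is the per-trait per-step probability of
    a horizontal transfer into a random lineage lacking it, active from
    ``hgt_onset`` (relative age) onward.
    """

    n_steps: int = 100
    births_per_step: float = 2.0
    loss: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.02, "B": 0.01, "E": 0.01})
    hgt_rate: float = 0.0
    hgt_onset: float = 0.5
    split_times: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        for sk, p in self.loss.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"loss[{sk}] outside [0,1]")
        if not 0.0 <= self.hgt_rate <= 1.0:
            raise SimulationError("hgt_rate outside [0,1]")
        if not 0.0 <= self.hgt_onset <= 1.0:
            raise SimulationError("hgt_onset outside [0,1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_traits: int = 200
    n_genomes: Mapping[str, int] = field(
        default_factory=lambda: {"A": 8, "B": 8, "E": 8})
    gamma: float = 2.0
    xmin: int = 1
    kernel_size: int = 10
    innovation_schedule: Sequence[tuple[int, int, float]] = ((0, 10**9, 0.1),)
    ma_params: MAParams = field(default_factory=MAParams)
    evo_params: EvoParams = field(default_factory=EvoParams)
    age_grid: float = 0.01  # ages quantized to this grid (0 disables)

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise SimulationError("gamma must exceed 1")
        if self.xmin < 1:
            raise SimulationError("xmin must be >= 1")
        for sk, n in self.n_genomes.items():
            if n < 2:
                raise SimulationError(f"need >= 2 lineages per superkingdom ({sk})")
        for lo, hi, p in self.innovation_schedule:
            if not 0.0 <= p <= 1.0:
                raise SimulationError("innovation probabilities must be in [0,1]")


def sample_discrete_powerlaw(gamma: float, xmin: int, n: int,
                             seed: int) -> list[int]:
    """n draws from the discrete power law P(k) ~ k**-gamma, k >= xmin."""
    if n < 0:
        raise SimulationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return [int(k) for k in sample_zipf(gamma, xmin, n, rng)]


def _p_new_at(schedule: Sequence[tuple[int, int, float]], step: int) -> float:
    for lo, hi, p in schedule:
        if lo <= step < hi:
            return p
    raise SimulationError(f"innovation schedule does not cover step {step}")


def simulate_kernel_growth(config: SimulationConfig,
                           n_steps: int = 10_000) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Two-probability vocabulary-growth stream (kernel reuse vs novelty).

    At each step a never-seen token is emitted with the schedule's novelty
    probability ``p_new``; otherwise an existing token is re-drawn with
    probability proportional to its current frequency (equivalently, uniform
    from the emission history).  Returns (stream, N, V) with V(N) the
    cumulative vocabulary curve — non-decreasing and <= N by construction.
    """
    if not config.innovation_schedule:
        raise SimulationError("empty innovation schedule")
    rng = np.random.default_rng(config.seed)
    stream: list[int] = []
    next_token = 0
    V = np.empty(n_steps, dtype=float)
    for step in range(n_steps):
        p_new = _p_new_at(config.innovation_schedule, step)
        if next_token == 0 or rng.random() < p_new:
            tok = next_token
            next_token += 1
        else:
            tok = stream[int(rng.integers(len(stream)))]
        stream.append(tok)
        V[step] = next_token
    N = np.arange(1, n_steps + 1, dtype=float)
    return stream, N, V


def simulate_ma_proteome(config: SimulationConfig) -> pd.DataFrame:
    """Proteins with k = 1..kmax domains and MA-scaled domain lengths.

    Domain lengths are A * k**b scaled by multiplicative lognormal noise
    exp(N(0, sigma^2)), keeping lengths positive.  Returns a long-format
    DataFrame (protein_id, k, domain_index, length).
    """
    p = config.ma_params
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for k in range(1, p.kmax + 1):
        base = p.A * k ** p.b
        for _ in range(p.n_per_k):
            noise = np.exp(rng.normal(0.0, p.sigma, size=k)) if p.sigma > 0 \
                else np.ones(k)
            for d, ln in enumerate(base * noise):
                rows.append((f"prot{pid:05d}", k, d, float(ln)))
            pid += 1
    return pd.DataFrame(rows, columns=["protein_id", "k", "domain_index", "length"])


# --------------------------------------------------------------------------
# vocabulary evolution
# --------------------------------------------------------------------------

def _lineage_schedule(n_genomes: Mapping[str, int], n_steps: int,
                      split_times: Mapping[str, Sequence[float]] | None):
    """Deterministic bifurcation schedule.

    One ancestral lineage splits into the A stem and the BE stem at relative
    age 0.1, the BE stem splits into B and E stems at 0.2, and each stem then
    bifurcates at evenly spaced times until its superkingdom reaches its
    target lineage count by age 0.8.
    """
    events: list[tuple[int, str]] = []  # (step, superkingdom stem to split)
    for sk in ("A", "B", "E"):
        n = n_genomes[sk]
        if split_times and sk in split_times:
            times = list(split_times[sk])
        else:
            start = {"A": 0.25, "B": 0.3, "E": 0.3}[sk]
            times = list(np.linspace(start, 0.8, max(n - 1, 1)))
        for t in times[:n - 1]:
            events.append((int(round(t * n_steps)), sk))
    return sorted(events, key=lambda e: (e[0], e[1]))


def simulate_vocabulary_evolution(config: SimulationConfig
                                  ) -> tuple[OccurrenceMatrix, AgeTable]:
    """Trait birth, vertical inheritance with loss, and horizontal transfer.

    Traits are born on a [0, 1] timeline (Poisson births per step) into one
    uniformly chosen extant lineage — before the first lineage split every
    birth is therefore ancestral and universal.  Lineages bifurcate on a fixed
    deterministic schedule (both daughters inherit the parent's traits); each
    present trait is lost per lineage per step with its superkingdom's loss
    probability, and from the horizontal-transfer onset age each trait jumps
    into one random lacking lineage with probability ``hgt_rate`` per step.
    Each trait's recorded age is its birth time, quantized to ``age_grid``.
    """
    ev = config.evo_params
    rng = np.random.default_rng(config.seed)
    n_steps = ev.n_steps

    # lineage bookkeeping: each lineage has a superkingdom ("R" = pre-split
    # root, "BE" = bacteria/eukarya stem); splits replace one lineage by two.
    lineages: list[str] = ["R"]  # superkingdom tag per lineage
    presence: dict[str, set[int]] = {}  # trait -> set of lineage indices
    ages: dict[str, float] = {}
    root_split = int(round(0.1 * n_steps))
    be_split = int(round(0.2 * n_steps))
    stem_events = _lineage_schedule(config.n_genomes, n_steps, ev.split_times)
    trait_no = 0

    def split(idx: int, tag_a: str, tag_b: str) -> None:
        lineages[idx] = tag_a
        new_idx = len(lineages)
        lineages.append(tag_b)
        for lin_set in presence.values():
            if idx in lin_set:
                lin_set.add(new_idx)

    event_ptr = 0
    for step in range(n_steps):
        t_rel = step / n_steps
        # scheduled splits
        if step == root_split:
            split(lineages.index("R"), "A", "BE")
        if step == be_split:
            split(lineages.index("BE"), "B", "E")
        while event_ptr < len(stem_events) and stem_events[event_ptr][0] <= step:
            ev_step, sk = stem_events[event_ptr]
            if ev_step == step and sk in lineages:
                cands = [i for i, tag in enumerate(lineages) if tag == sk]
                if 0 < len(cands) < config.n_genomes[sk]:
                    split(cands[int(rng.integers(len(cands)))], sk, sk)
            event_ptr += 1

        # births: Poisson number of new traits into one random extant lineage
        for _ in range(rng.poisson(ev.births_per_step)):
            if trait_no >= config.n_traits:
                break
            tid = f"trait{trait_no:05d}"
            trait_no += 1
            born_in = int(rng.integers(len(lineages)))
            presence[tid] = {born_in}
            age = t_rel
            if config.age_grid > 0:
                age = round(age / config.age_grid) * config.age_grid
            ages[tid] = min(max(age, 0.0), 1.0)

        # vertical loss, per lineage per trait
        for tid, lin_set in presence.items():
            if not lin_set:
                continue
            # stems ("R", "BE") lose nothing unless a rate is configured for them
            lost = {i for i in lin_set
                    if rng.random() < ev.loss.get(lineages[i], 0.0)}
            lin_set -= lost

        # horizontal transfer after onset
        if ev.hgt_rate > 0 and t_rel >= ev.hgt_onset:
            for tid, lin_set in presence.items():
                if not lin_set:
                    continue
                if rng.random() < ev.hgt_rate:
                    lacking = [i for i in range(len(lineages)) if i not in lin_set]
                    if lacking:
                        lin_set.add(lacking[int(rng.integers(len(lacking)))])

    # force any not-yet-split stems to their genome counts (pad by final split)
    for sk in ("A", "B", "E"):
        while lineages.count(sk) < config.n_genomes[sk] and sk in lineages:
            split(lineages.index(sk), sk, sk)

    genome_ids: list[str] = []
    sk_labels: dict[str, str] = {}
    counters = {"A": 0, "B": 0, "E": 0}
    col_of: dict[int, str] = {}
    for i, tag in enumerate(lineages):
        sk = tag if tag in ("A", "B", "E") else "A"
        gid = f"{sk}{counters[sk]:03d}"
        counters[sk] += 1
        genome_ids.append(gid)
        sk_labels[gid] = sk
        col_of[i] = gid

    trait_ids = sorted(ages, key=lambda t: (ages[t], t))
    mat = pd.DataFrame(0, index=trait_ids, columns=genome_ids, dtype=int)
    for tid in trait_ids:
        for i in presence.get(tid, ()):
            mat.loc[tid, col_of[i]] = 1
    return (OccurrenceMatrix(counts=mat, superkingdoms=sk_labels),
            AgeTable(ages))


# --------------------------------------------------------------------------
# synthetic GO terms
# --------------------------------------------------------------------------

DEFAULT_POOLS: dict[str, dict[str, Sequence[str]]] = {
    "ABE": {"heads": ("binding", "activity"),
            "modifiers": ("ion", "transferase", "hydrolase", "compound",
                          "small molecule", "cofactor")},
    "BE": {"heads": ("activity",),
           "modifiers": ("channel", "transporter", "regulator", "inhibitor")},
    "E": {"heads": ("constituent", "binding"),
          "modifiers": ("structural", "cytoskeleton", "muscle", "drug")},
}


def make_synthetic_go_terms(n_terms: int, seed: int,
                            pools: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
                            ages: Sequence[float] | None = None,
                            age_grid: float = 0.01) -> list[TermRecord]:
    """GO-style term records with head-final names drawn from word pools.

    Each term's name is 1-3 modifier words (sampled from its Venn group's
    modifier pool) followed by a head word; names are guaranteed to round-trip
    through the word-cloud tokenizer.  Deterministic under the seed.
    """
    pools = pools or DEFAULT_POOLS
    for g, pool in pools.items():
        if not pool.get("heads") or not pool.get("modifiers"):
            raise SimulationError(f"empty word pool for group {g}")
    rng = np.random.default_rng(seed)
    groups = sorted(pools)
    out: list[TermRecord] = []
    for i in range(n_terms):
        g = groups[int(rng.integers(len(groups)))]
        heads = list(pools[g]["heads"])
        mods = list(pools[g]["modifiers"])
        head = heads[int(rng.integers(len(heads)))]
        n_mod = int(rng.integers(1, 3))
        chosen = [mods[int(rng.integers(len(mods)))] for _ in range(n_mod)]
        name = " ".join(chosen + [head])
        if ages is not None:
            age = float(ages[i % len(ages)])
        else:
            age = float(rng.random())
            if age_grid > 0:
                age = round(age / age_grid) * age_grid
        age = min(max(age, 0.0), 1.0)
        rec = TermRecord(term_id=f"GO:{7000000 + i}", name=name, age=age, group=g)
        tokenize(rec.name, rec.term_id)  # round-trip guard
        out.append(rec)
    # duplicate names must not conflict in age: keep first age for repeats
    seen: dict[str, float] = {}
    for rec in out:
        if rec.name in seen:
            rec.age = seen[rec.name]
        else:
            seen[rec.name] = rec.age
    return out
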