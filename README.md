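# molvocab

Quantitative linguistics of proteome and functionome vocabularies.

Comparative genomics treats the protein domains encoded in genomes — and the
Gene Ontology (GO) terms that describe their molecular functions — as the
*words* of a molecular language. `molvocab` is a Python library for analyzing
such vocabularies: it fits the three statistical laws that govern them,
censuses how traits are shared across the superkingdoms Archaea (A), Bacteria
(B) and Eukarya (E), traces trait histories along evolutionary timelines, and
draws "causal word clouds" that place the lexical units of GO term names on
the timeline. It is aimed at evolutionary bioinformaticians studying genome
content evolution, vocabulary compression, and the history of molecular
functions.

## The models

* **Zipf's law.** The number of traits occurring `k` times follows
  `f(k) = C·k^-γ`. The tail exponent γ is estimated by discrete maximum
  likelihood on `k ≥ xmin` (Hurwitz-zeta normalization), with a
  Kolmogorov–Smirnov distance `D` and a seeded semiparametric bootstrap
  p-value as goodness diagnostics. No verdict that "a power law holds" is
  emitted — only the statistics.
* **Heaps' law.** Vocabulary size grows sublinearly with database size,
  `V(N) = K·N^β` with β < 1, often in several regimes. Regimes are discovered
  by an exact dynamic program over log–log breakpoints with BIC model
  selection.
* **Menzerath–Altmann law.** "The greater the whole, the smaller its
  constituents": mean domain length in proteins with `k` domains follows
  `z_k = A·k^b` with b < 0, fitted by weighted least squares of `log z_k` on
  `log k` with the per-`k` protein counts as weights.
* **Distribution index and Venn groups.** For a trait and a genome set, the
  index `f` is the fraction of genomes carrying the trait (exact rationals,
  so `f = 1` and thresholds like `f > 0.9` are unambiguous). Traits are
  partitioned into the seven Venn taxonomic groups ABE, AB, AE, BE, A, B, E
  by which superkingdoms contain them; partial partitions (e.g. totals plus a
  few groups) are completed by solving the linear system exactly.
* **Timelines.** Relative ages on a 0 (origin) → 1 (present) scale come from
  rooted trees as normalized root-to-node distances, convertible to Gy before
  present by a linear clock. The package tracks `f` against age, first
  complete losses (`f = 0`), and the age ordering of Venn groups.
* **Causal word clouds.** GO term names are tokenized head-finally (head,
  sub-head, modifier chain); each lexical unit is placed at the age of the
  oldest term naming it (dominance, x) and stacked by its position in the
  word string (precedence, y), sized by frequency, colored by Venn group,
  outlined when repeated, and rendered to byte-stable SVG.

A `simulate` module generates all of these inputs synthetically — Zipfian
spectra, kernel/novelty token streams, MA-scaled domain lengths, and
presence/absence matrices shaped by vertical loss plus late horizontal
transfer — so every analysis is testable end-to-end without external data.

## Worked example

The four oldest level-2 molecular-function GO terms, with their relative
ages, pin the dominance axis of the word cloud:

```python
from molvocab import TermRecord, dominance_ages, layout

terms = [
    TermRecord("GO:0043167", "ion binding", 0.0, "ABE"),
    TermRecord("GO:0097159", "organic cyclic compound binding", 0.02, "ABE"),
    TermRecord("GO:0016740", "transferase activity", 0.068, "ABE"),
    TermRecord("GO:0060589", "nucleoside-triphosphatase regulator activity",
               0.407, "ABE"),
]
print(dominance_ages(terms))
```

prints

```
{'binding': 0.0, 'ion': 0.0, 'compound': 0.02, 'organic cyclic': 0.02,
 'activity': 0.068, 'transferase': 0.068, 'regulator': 0.407,
 'nucleoside-triphosphatase': 0.407}
```

"binding" and "ion" anchor the timeline origin; "regulator" enters at age
0.407 and is laid out on the row of "activity" (which first appeared at
0.068 with "transferase activity"). Completing the terminal
molecular-function Venn partition from the Archaea and Bacteria totals (638
and 1,060) and the directly given groups (ABE = 526, BE = 272, A = 1,
B = 162, E = 852):

```python
from molvocab import venn_complete
part, _ = venn_complete({"total_A": 638, "total_B": 1060, "ABE": 526,
                         "BE": 272, "A": 1, "B": 162, "E": 852})
print(part.counts["AB"], part.counts["AE"], part.total("E"))
# 100 11 1661
```

solves AB = 100 and AE = 11 and yields a Eukarya total of 1,661 terms — the
compressed microbial vocabularies against the expanded eukaryal one.

The `examples/` directory holds one short script per capability
(`fit_language_laws.py`, `occurrence_census.py`, `evolution_timeline.py`,
`causal_wordcloud.py`, `persistence_triangle.py`); each builds a small input,
runs the method and prints what the numbers mean. A thin CLI (`molvocab`)
exposes the same operations as subcommands (`sim`, `findex`, `venn`,
`venn-complete`, `fit-zipf`, `fit-heaps`, `fit-ma`, `ages`, `levels`,
`timeline`, `cloud`, `triangle`).

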