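import numpy as np
import pandas as pd
import pytest

from molvocab import OccurrenceMatrix, TermRecord


@pytest.fixture
def worked_example_terms() -> list[TermRecord]:
    """The four level-2 molecular-function terms with their relative ages."""
    return [
        TermRecord("GO:0043167", "ion binding", 0.0, "ABE"),
        TermRecord("GO:0097159", "organic cyclic compound binding", 0.02, "ABE"),
        TermRecord("GO:0016740", "transferase activity", 0.068, "ABE"),
        TermRecord("GO:0060589", "nucleoside-triphosphatase regulator activity",
                   0.407, "ABE"),
    ]


def random_matrix(rng: np.random.Generator, n_traits: int, n_genomes: int,
                  density: float = 0.4, max_count: int = 3) -> OccurrenceMatrix:
    """Random occurrence matrix with random superkingdom labels."""
    counts = rng.integers(1, max_count + 1, size=(n_traits, n_genomes))
    counts = counts * (rng.random((n_traits, n_genomes)) < density)
    traits = [f"t{i}" for i in range(n_traits)]
    genomes = [f"g{j}" for j in range(n_genomes)]
    labels = {g: "ABE"[int(rng.integers(3))] for g in genomes}
    return OccurrenceMatrix(
        counts=pd.DataFrame(counts, index=traits, columns=genomes, dtype=int),
        superkingdoms=labels)


@pytest.fixture
def toy_matrix() -> OccurrenceMatrix:
    """5 traits x 4 genomes; t1 present in 3 of the 4 genomes."""
    counts = pd.DataFrame(
        [[1, 1, 1, 0],   # t1: 3 of 4
         [1, 1, 1, 1],   # t2: all
         [0, 0, 0, 0],   # t3: none
         [2, 0, 0, 0],   # t4: one
         [0, 0, 3, 1]],  # t5: two
        index=["t1", "t2", "t3", "t4", "t5"],
        columns=["gA1", "gA2", "gB1", "gE1"], dtype=int)
    labels = {"gA1": "A", "gA2": "A", "gB1": "B", "gE1": "E"}
    return OccurrenceMatrix(counts=counts, superkingdoms=labels)
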