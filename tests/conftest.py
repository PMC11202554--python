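import numpy as np
import pytest

from snppanel import (
    ColonyScenario,
    GenotypeMatrix,
    simulate_colonies,
    simulate_variant_set,
)


def make_matrix(pop_calls: dict[str, list[list]], loci: list[str]) -> GenotypeMatrix:
    """Build a matrix from {population: [per-sample call rows]}.

    Calls are given as compact strings ("AG") or None.
    """
    from snppanel import parse_call

    samples, populations, rows = [], {}, []
    for pop, sample_rows in pop_calls.items():
        for i, row in enumerate(sample_rows):
            name = f"{pop}{i + 1}"
            samples.append(name)
            populations[name] = pop
            rows.append([parse_call(c) if isinstance(c, str) else c for c in row])
    calls = np.empty((len(samples), len(loci)), dtype=object)
    for i, row in enumerate(rows):
        calls[i, :] = row
    return GenotypeMatrix(samples, loci, calls, populations)


@pytest.fixture(scope="session")
def genotyping_sim():
    """A 219-locus genotyping run with the three planted failure modes."""
    return simulate_colonies(ColonyScenario.genotyping_run(seed=11))


@pytest.fixture(scope="session")
def variant_sim():
    """Discovery variant set: 20 perfect loci + 5x20 one-fault decoys."""
    return simulate_variant_set()
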