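import numpy as np
import pandas as pd
import pytest

import famblup as fb


@pytest.fixture(scope="session")
def small_map():
    return fb.generate_genetic_map(5, 60, 100.0, seed=11)


@pytest.fixture(scope="session")
def founders(small_map):
    return fb.generate_founders(40, small_map, seed=12)


@pytest.fixture(scope="session")
def small_program():
    """A scaled-down breeding program shared by the validation tests."""
    return fb.simulate_breeding_program(
        n_families=8,
        progeny_per_family=20,
        n_pool=100,
        n_chromosomes=5,
        markers_per_chromosome=60,
        n_qtl=40,
        n_snp=200,
        seed=21,
    )


def random_pedigree(rng, n_founders=4, n_generations=3, per_generation=5):
    """Random multi-generation pedigree for oracle tests."""
    rows = [(f"f{i}", None, None) for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for g in range(n_generations):
        new = []
        for k in range(per_generation):
            p1, p2 = rng.choice(ids, size=2, replace=False)
            new.append((f"g{g}_{k}", p1, p2))
        rows += new
        ids += [r[0] for r in new]
    return fb.Pedigree(pd.DataFrame(rows, columns=["id", "parent1", "parent2"]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
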