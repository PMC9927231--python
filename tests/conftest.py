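"""Shared fixtures: scaled and study-sized synthetic cytotype pairs.

The `mini` configuration keeps the quadripartite architecture, variant
density and inversion of the study design at a quarter of the genome size,
which makes implant-recover tests fast; the `study` configuration uses the
full published dimensions and is shared (module-scoped) by the acceptance
tests.
"""

import numpy as np
import pytest

from plastotyper.simulate import SimulationConfig, make_cytotype_pair

MINI = dict(genome_len=40_000, ir_len=8_000, ssc_len=4_000,
            n_diag_snps=40, n_diag_indels=10, inversion_len=230,
            n_subgroup_variants=20)


def mini_config(seed: int = 1, **overrides) -> SimulationConfig:
    params = {**MINI, **overrides}
    return SimulationConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def mini_pair():
    cfg = mini_config(seed=1)
    return (*make_cytotype_pair(cfg), cfg)


@pytest.fixture(scope="session")
def study_pair():
    cfg = SimulationConfig(seed=1)
    return (*make_cytotype_pair(cfg), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n: int, p=(0.32, 0.18, 0.18, 0.32)) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])
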