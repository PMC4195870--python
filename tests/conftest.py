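import numpy as np
import pytest

from polystr import Config, SequenceRecord, standard_scenario


@pytest.fixture(scope="session")
def scenario_config() -> Config:
    # top_k large enough that selection never truncates the planted candidates
    return Config(top_k=60)


@pytest.fixture(scope="session")
def scenario(scenario_config):
    """A compact planted-truth dataset shared across tests (seed-fixed)."""
    assembly, truth, variants = standard_scenario(
        11, n_poly=8, n_fixed=4, n_mono=3, n_trap_multiple=2, n_trap_qual=2,
        n_trap_flankn=2, n_contigs=2, contig_len=30_000, config=scenario_config,
    )
    return assembly, truth, variants


def random_record(rng: np.random.Generator, length: int, gc: float = 0.4, name: str = "rand") -> SequenceRecord:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return SequenceRecord(name, seq)
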