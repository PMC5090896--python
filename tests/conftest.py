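import numpy as np
import pytest
from hypothesis import settings

from chimerabench.mutate import MutationRates, mutate_genome
from chimerabench.reference import ReferenceBundle, ReferenceSpec, build_reference

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequences(lengths: dict[str, int], seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {
        name: _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
        for name, n in lengths.items()
    }


def flat_bundle(lengths: dict[str, int], seed: int = 0) -> ReferenceBundle:
    """Annotation-free genome (for mutation-rate measurements)."""
    return ReferenceBundle(sequences=random_sequences(lengths, seed), genes=[], repeats=[])


TINY_SPEC = ReferenceSpec(
    n_chroms=2,
    chrom_length=120_000,
    n_genes=24,
    exons_per_gene_range=(3, 5),
    exon_len_range=(80, 200),
    intron_len_range=(100, 400),
    repeat_fraction=0.03,
    pseudogene_fraction=0.08,
)


@pytest.fixture(scope="session")
def tiny_reference():
    return build_reference(TINY_SPEC, seed=7)


@pytest.fixture(scope="session")
def tiny_mutated(tiny_reference):
    return mutate_genome(tiny_reference, MutationRates(), n_translocations=3, seed=11)
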