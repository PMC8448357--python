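import numpy as np
import pytest

from msm_anatomy.seqio_align import SeqRecord

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def monomer137():
    return random_seq(np.random.default_rng(7), 137)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete simulation shared by read-only tests."""
    from msm_anatomy.synthetic_data import SimulationConfig, simulate

    cfg = SimulationConfig(
        seed=11,
        ancestor_genome_length=400_000,
        n_autosomes=2,
        derived_expansion_copies=400,
        n_microchromosomes=2,
        msm_length=30_000,
        n_planted_genes=12,
        integrity_mix=(0.25, 0.25, 0.5),
        n_male_specific_genes=2,
        n_male_biased_genes=3,
        n_background_genes=100,
        n_decoy_genes=4,
        reads_per_sample=300,
        msm_coverage=6.0,
    )
    return simulate(cfg)


def make_hsp(**kw):
    """Hsp with sensible defaults for rule-level tests."""
    from msm_anatomy.seqio_align import Hsp

    defaults = dict(
        query_id="q",
        target_id="t",
        q_start=0,
        q_end=100,
        t_start=0,
        t_end=100,
        strand="+",
        aligned_length=100,
        identities=100,
        mapq=60,
        score=200.0,
    )
    defaults.update(kw)
    return Hsp(**defaults)
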