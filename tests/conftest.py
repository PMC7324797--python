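import numpy as np
import pytest

from bsmeth.simulate import (
    SimulationConfig,
    simulate_dataset,
    uniform_rates,
    CONTEXT_RATES,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-sized two-group dataset: 50 kb over two contigs, 8 genes."""
    return SimulationConfig(
        seed=11,
        contig_lengths={"cA": 30_000, "cB": 20_000},
        gene_count=8,
        exons_per_gene=3,
        exon_length=300,
        intron_length=150,
        rates=uniform_rates(by_context=CONTEXT_RATES),
        phi=0.02,
        coverage_mean=30.0,
        groups=("G1", "G2"),
        replicates=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_sequence(rng, length: int, with_n: float = 0.0) -> str:
    bases = "ACGT" if with_n == 0 else "ACGTN"
    p = [0.25] * 4 if with_n == 0 else [(1 - with_n) / 4] * 4 + [with_n]
    return "".join(rng.choice(list(bases), size=length, p=p))


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def oracle_context(seq: str, pos: int, strand: str) -> str:
    """Independent string-based context classifier (test oracle).

    Works on the strand's own 5'->3' reading; returns the context label.
    """
    if strand == "-":
        seq = revcomp(seq)
        pos = len(seq) - 1 - pos
    window = (seq[pos : pos + 3] + "NN")[:3]
    assert window[0] == "C"
    if window[1] == "G":
        return "CpG"
    if window[1] == "N":
        return "UNDEFINED"
    if window[2] == "G":
        return "CHG"
    if window[2] == "N":
        return "UNDEFINED"
    return "CHH"
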