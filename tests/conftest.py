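import pytest

from ccdbg import PanGenomeText, build_graph, build_index
from ccdbg.synth import SynthConfig, generate_pan_genome

EXAMPLE_SEQS = ["CTATGTC", "ATATGTTGGTC"]


@pytest.fixture(scope="session")
def example_text():
    return PanGenomeText.from_sequences(EXAMPLE_SEQS, ["seq0", "seq1"])


@pytest.fixture(scope="session")
def example_index(example_text):
    return build_index(example_text, s_sa=16)


@pytest.fixture(scope="session")
def example_graph(example_index, example_text):
    """k=3, checkpoint sparseness 2 (the fully featured worked example)."""
    return build_graph(example_index, example_text, k=3, s_cp=2)


@pytest.fixture(scope="session")
def example_graph_baseline(example_index, example_text):
    """k=3 without any checkpoint k-mers."""
    return build_graph(example_index, example_text, k=3, s_cp=None)


def make_pan_genome(seed, base_length=1500, n_strains=3, sub=0.01, indel=0.002):
    cfg = SynthConfig(
        base_length=base_length,
        n_strains=n_strains,
        substitution_rate=sub,
        indel_rate=indel,
        seed=seed,
        k_guard=24,
    )
    text, truth = generate_pan_genome(cfg)
    return cfg, text, truth


@pytest.fixture(scope="session")
def small_corpus():
    """A few small pan-genomes with their indexes, for oracle comparisons."""
    out = []
    for seed, k in [(11, 5), (12, 11), (13, 21)]:
        _cfg, text, _truth = make_pan_genome(seed, base_length=900, n_strains=3)
        out.append((text, build_index(text, s_sa=16), k))
    return out
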