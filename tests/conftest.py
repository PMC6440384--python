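import pytest

from gdrep import (SimulationConfig, default_trg_usage, load_reference,
                   simulate_repertoire)


@pytest.fixture(scope="session")
def ref():
    return load_reference("builtin")


@pytest.fixture(scope="session")
def trg_sim(ref):
    """Error-free TRG simulation with canonical spike (shared across
    round-trip and statistics tests)."""
    v_usage, j_usage = default_trg_usage(ref)
    cfg = SimulationConfig(chain="TRG", n_reads=800, v_usage=v_usage,
                           j_usage=j_usage, error_rate=0.0,
                           canonical_spike=0.25, seed=101)
    return simulate_repertoire(ref, cfg)


@pytest.fixture(scope="session")
def trg_annotated(ref, trg_sim):
    from gdrep import annotate_reads
    return annotate_reads(trg_sim.reads, ref, "TRG")
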