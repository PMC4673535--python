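import pytest

from mirtarnet.datasets import ArrayDesign, TruthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    design = ArrayDesign(n_mirna_probes=400, n_mrna_probes=1500)
    cfg = TruthConfig(
        n_up_mirna=40,
        n_down_mirna=10,
        n_up_mrna=60,
        n_down_mrna=120,
        n_linked_mirna=20,
        n_linked_genes=60,
        n_decoy_associations=100,
    )
    return generate_dataset(design, cfg, seed=11)
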