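import numpy as np
import pytest

from mfr import SyntheticSpec, make_resources


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_resources():
    """A small mixed-kind synthetic bundle shared across tests."""
    spec = SyntheticSpec(
        n_genes=60, n_samples=60, n_modules=6, module_coexpression=0.8,
        annotation_coherence=0.9, seed=11,
    )
    kinds = {0: "both", 1: "both", 2: "expr_only", 3: "knowledge_only",
             4: "both", 5: "knowledge_only"}
    return make_resources(spec, module_kinds=kinds)
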