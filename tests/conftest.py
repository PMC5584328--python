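import numpy as np
import pytest

import invarnorm as iv


@pytest.fixture(scope="session")
def default_fixture():
    """Canonical synthetic study (2000 genes, 3 conditions x 3 replicates)."""
    counts, lengths, truth = iv.simulate_dataset(iv.SimulationConfig(seed=0))
    return counts, lengths, truth


@pytest.fixture(scope="session")
def normalized_fixture(default_fixture):
    """Default fixture pushed through the full selector + corrector pipeline."""
    counts, lengths, truth = default_fixture
    rpkm = iv.compute_rpkm(counts, lengths)
    with np.errstate(all="ignore"):
        solution, invariant_ids = iv.select_invariant_genes(rpkm)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = iv.normalize_matrix(rpkm, invariant_ids)
    return counts, lengths, truth, rpkm, solution, invariant_ids, result
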