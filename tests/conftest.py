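import numpy as np
import pytest

import traffiq as tq


@pytest.fixture(scope="session")
def noiseless_spec() -> tq.FieldSpec:
    return tq.FieldSpec(cargo_inside_fraction=0.7, noise_sd=0.0, n_cells=6, seed=3)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_spec):
    return tq.generate_field(noiseless_spec)


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_field):
    field, truth = noiseless_field
    cells, masks, assignment, fu_in, fu_out = tq.segment_field(field)
    return field, truth, cells, masks, assignment, fu_in, fu_out


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 1.0
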