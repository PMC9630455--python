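import numpy as np
import pytest

import slideuq as s


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset reused by read-only tests."""
    cfg = s.SimulationConfig(n_slides_per_class=30, tiles_per_slide=40, seed=11)
    return s.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_tile_results(small_dataset):
    return s.estimate_all(small_dataset.ensembles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_ensemble(tile_id="t0", slide_id="s0", patient_id="p0", label=0,
                  values=(0.1, 0.2, 0.3)):
    return s.TileEnsemble(
        tile_id=tile_id, slide_id=slide_id, patient_id=patient_id,
        label=label, pass_values=tuple(values),
    )
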