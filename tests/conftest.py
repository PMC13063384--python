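import numpy as np
import pytest

from caredea.simulate import PanelSimSpec, generate_dmu_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_panel():
    """Seeded 6-DMU CRS panel with three planted inefficiencies."""
    panel, truth = generate_dmu_panel(
        PanelSimSpec(
            n_dmu=6,
            n_inputs=2,
            n_outputs=1,
            inefficiency_factors=(1.0, 0.8, 1.0, 0.65, 1.0, 0.9),
            seed=7,
        )
    )
    return panel, truth
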