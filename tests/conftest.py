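import math

import pytest

from cdmas.synthetic_data import (
    MarkerModel,
    PanelConfig,
    generate_panel,
    preset,
    toy_marker_def,
)


@pytest.fixture
def toy_marker():
    """200-bp synthetic CAPS assay with one EcoRI site at offset 80."""
    return toy_marker_def("toy")


@pytest.fixture
def early_panel():
    """Deterministic EARLY-season synthetic panel (seed 11)."""
    return generate_panel(preset("EARLY", seed=11))


@pytest.fixture
def late_panel():
    return generate_panel(preset("LATE", seed=11))


@pytest.fixture
def noiseless_config():
    """Tiny fully deterministic panel: one marker of effect -1, no noise.

    Five planted all-low cultivars (expected Cd = 0.3*e^-1 < 0.2) and five
    high cultivars at exactly the baseline 0.3.
    """
    return PanelConfig(
        n_cultivars=10,
        field_ids=("A", "B"),
        markers=(MarkerModel("m1", 0.5, -1.0),),
        baseline_log_cd=math.log(0.3),
        field_effects={"A": 0.0, "B": 0.0},
        gxe_sd=0.0,
        noise_sd=0.0,
        n_replicates=3,
        seed=5,
        haplotypes=(((True,), 5), ((False,), 5)),
    )
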