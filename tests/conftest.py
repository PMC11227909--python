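import dataclasses

import pytest

from nicheoverlap.synthetic import default_config, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-size synthetic two-species dataset shared across tests."""
    cfg = default_config(seed=42)
    cfg = dataclasses.replace(
        cfg, n_nests_A=40, n_nests_B=20, n_fecal_A=14, n_fecal_B=10
    )
    cfg.diet.reads_per_sample_mean = 2000
    return generate(cfg)
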