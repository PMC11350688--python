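import pytest

from camtrap_rem.synth import SyntheticDatasetConfig, generate_detection_table


@pytest.fixture(scope="session")
def small_survey():
    """A one-year, 12-station synthetic survey with known truth (seeded)."""
    cfg = SyntheticDatasetConfig(n_stations=12, seed=42)
    return generate_detection_table(cfg)
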