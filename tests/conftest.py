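import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pharmsig import synth, vocab

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def binary_hierarchy() -> vocab.Hierarchy:
    """Perfect binary 5-level tree: 1 SOC, 2 HLGT, 4 HLT, 8 PT, 16 LLT."""
    return synth.gen_hierarchy(synth.SyntheticConfig(hierarchy_shape=(2, 2, 2, 2)))


@pytest.fixture(scope="session")
def vasculitis_hierarchy() -> vocab.Hierarchy:
    """A 5-level chain whose high-level term covers one specific leaf."""
    rows = [
        ("MDV00", "C0V00", "SOC", "Vascular disorders", ""),
        ("MDV01", "C0V01", "HLGT", "Vasculitides and related", "MDV00"),
        ("MDV02", "C0V02", "HLT", "Vasculitides", "MDV01"),
        ("MDV03", "C0V03", "PT", "Cutaneous vasculitis", "MDV02"),
        ("MDV04", "C0V04", "LLT", "Skin vasculitis NOS", "MDV03"),
    ]
    df = pd.DataFrame(rows, columns=vocab.HIERARCHY_COLUMNS)
    return vocab._build_hierarchy(df)


@pytest.fixture(scope="session")
def small_scenario() -> synth.Scenario:
    """A reduced copy of the bundled scenario for fast integration tests."""
    cfg = synth.default_config(seed=7, n_reports=1500, n_patients=500)
    return synth.generate_scenario(cfg)
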