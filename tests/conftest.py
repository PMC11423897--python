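import pandas as pd
import pytest
from hypothesis import settings

from paleodiv.synthetic import GroupScenario, ScenarioSpec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """Hand-written occurrence table: 8 rows, one duplicated occurrence,
    one reworked record, corals with ecology, two groups, two intervals."""
    rows = [
        # taxon, rank, genus, group, locality, region, interval, reworked, eco
        ("Aa bb", "species", "Aa", "ostracods", "L1", "Western Mediterranean", "Tortonian", "false", ""),
        ("Aa bb", "species", "Aa", "ostracods", "L1", "Western Mediterranean", "Tortonian", "false", ""),  # dup
        ("Aa cc", "species", "Aa", "ostracods", "L1", "western_mediterranean", "Tortonian", "false", ""),
        ("Dd ee", "species", "Dd", "ostracods", "L2", "eastern_mediterranean", "Zanclean", "true", ""),
        ("Dd ee", "species", "Dd", "ostracods", "L3", "po_adriatic", "Zanclean", "false", ""),
        ("Ff gg", "species", "Ff", "corals", "L1", "western_mediterranean", "Tortonian", "false", "z"),
        ("Hh ii", "species", "Hh", "corals", "L2", "eastern_mediterranean", "Tortonian", "false", "az"),
        ("Jj", "genus", "Jj", "bivalves", "L3", "po_adriatic", "pre-evaporitic Messinian", "false", ""),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "taxon_name", "rank", "genus", "group", "locality_id",
            "region", "interval", "reworked", "coral_ecology",
        ],
    )


@pytest.fixture
def tiny_csv(tmp_path, tiny_frame):
    path = tmp_path / "occurrences.csv"
    tiny_frame.to_csv(path, index=False)
    return path


@pytest.fixture
def deep_uniform_scenario() -> ScenarioSpec:
    """One group, even abundances, deep sampling, programmed turnover 0.40."""
    return ScenarioSpec(
        groups=(GroupScenario("ostracods", 100, 5000),),
        turnover_frac=0.40,
        nested_loss_frac=0.0,
        region_mix=(0.34, 0.33, 0.33),
        abundance_model="uniform",
        localities=300,
        reworked_frac=0.0,
        seed=11,
    )


@pytest.fixture
def nested_loss_scenario() -> ScenarioSpec:
    """Pure nested loss: half the pool disappears each transition."""
    return ScenarioSpec(
        groups=(GroupScenario("bivalves", 100, 5000),),
        turnover_frac=0.0,
        nested_loss_frac=0.5,
        region_mix=(0.34, 0.33, 0.33),
        abundance_model="uniform",
        localities=300,
        reworked_frac=0.0,
        seed=13,
    )
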