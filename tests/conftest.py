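import hypothesis
import numpy as np
import pandas as pd
import pytest

import nanoherit as nh

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=25,
    deadline=None, suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def sorghum_design() -> nh.DesignSpec:
    return nh.DesignSpec.sorghum()


@pytest.fixture(scope="session")
def small_design() -> nh.DesignSpec:
    """2 x 2 x 2 x 2 x 3 design: cheap enough for repeated REML fits."""
    return nh.DesignSpec(
        varieties=("V1", "V2"),
        sections_by_variety={"V1": ("Leaf", "Stem"), "V2": ("Leaf", "Stem")},
        energy_levels=("Low", "High"),
        n_duplicates=2,
        n_strips=3,
    )


@pytest.fixture(scope="session")
def interior_design() -> nh.DesignSpec:
    """Enough factor levels that EMS solutions stay strictly positive."""
    return nh.DesignSpec(
        varieties=tuple(f"V{i}" for i in range(1, 6)),
        sections_by_variety={f"V{i}": ("Leaf", "Stem") for i in range(1, 6)},
        energy_levels=("E1", "E2", "E3", "E4"),
        n_duplicates=2,
        n_strips=3,
    )


#: Generating components that keep every EMS stratum solution interior on
#: the interior_design at the seeds used in tests.
INTERIOR_COMPONENTS = {
    "Variety": 100.0, "Section:Variety": 80.0, "Energy": 120.0,
    "Nanopaper": 40.0, "Strip:Nanopaper": 30.0, "Residual": 20.0,
}


def make_oneway_table(groups: dict[str, list[float]]) -> nh.ObservationTable:
    """One-way layout encoded in the variety column."""
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append((g, "s", "e", "1", str(i + 1), "m", v))
    df = pd.DataFrame(rows, columns=["variety", "section", "energy",
                                     "nanopaper", "strip", "metric", "value"])
    return nh.ObservationTable(df)


@pytest.fixture()
def oneway_table() -> nh.ObservationTable:
    """Hand example: groups A={1,2,3}, B={5,6,7} -> between 23/3, within 1."""
    return make_oneway_table({"A": [1, 2, 3], "B": [5, 6, 7]})


@pytest.fixture(scope="session")
def toy_long_csv(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("data") / "toy.csv"
    df = pd.DataFrame({
        "variety": ["A"] * 3 + ["B"] * 3,
        "section": ["Leaf"] * 6,
        "energy": ["Low", "Low", "High", "Low", "Low", "High"],
        "nanopaper": ["1", "2", "1", "1", "2", "1"],
        "strip": ["1", "1", "1", "1", "1", "1"],
        "tensile_index": [10.0, 12.0, 14.0, 20.0, 22.0, 24.0],
    })
    df.to_csv(path, index=False)
    return str(path)
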