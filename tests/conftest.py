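import pandas as pd
import pytest

from devtoxglr.gating import compute_plate_thresholds, summarize_wells
from devtoxglr.layouts import make_screen_layout
from devtoxglr.simulate import ChemicalEffectSpec, SimConfig, simulate_screen

HILL_CHEM = ChemicalEffectSpec(
    "hillchem", sox17_top=0.8, sox17_log10_ac50=0.0, sox17_hill=1.0
)
NULL_CHEM = ChemicalEffectSpec("nullchem", truth_class="negative")


@pytest.fixture(scope="session")
def screen_layout():
    return make_screen_layout(
        "plate01",
        ["hillchem", "nullchem"],
        n_replicate_wells=4,
        control_wells_per_role=12,
    )


@pytest.fixture(scope="session")
def screen_cells(screen_layout) -> pd.DataFrame:
    """One simulated plate: a SOX17-suppressing chemical plus a null."""
    return simulate_screen([screen_layout], [HILL_CHEM, NULL_CHEM], SimConfig(seed=11))


@pytest.fixture(scope="session")
def screen_wells(screen_cells, screen_layout) -> pd.DataFrame:
    thr = compute_plate_thresholds(screen_cells, screen_layout)
    return summarize_wells(screen_cells, thr, screen_layout)
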