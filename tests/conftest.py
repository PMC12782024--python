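import numpy as np
import pandas as pd
import pytest

from tempobisect._rng import substream
from tempobisect.cohort import clock_from_targets, simulate_response
from tempobisect.design import ALL_CONDITIONS, DURATIONS, TrialSpec


def simulate_counts(
    bp: float,
    wr: float,
    lapse: float = 0.0,
    n_per_cell: int = 8,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Counts table for one condition simulated from the clock model."""
    cond = ALL_CONDITIONS[0]
    clock = clock_from_targets({cond: bp}, {cond: wr}, lapse=lapse)
    if rng is None:
        rng = substream(seed, "test-counts")
    rows = []
    for d in DURATIONS:
        trial = TrialSpec("experimental", 0, cond, "x", d, 2.0)
        n_long = sum(
            simulate_response(clock, trial, rng) == "long" for _ in range(n_per_cell)
        )
        rows.append({"duration_s": d, "n_long": n_long, "n_trials": n_per_cell})
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_cohort_spec():
    """A scaled-down cohort (16 participants, 4 blocks) for pipeline tests."""
    from tempobisect.cohort import CohortSpec, GroupSpec, GROUP_BP, GROUP_WR

    ns = {"controls": 3, "AD": 3, "lvPPA": 3, "nfvPPA": 3, "svPPA": 2, "bvFTD": 2}
    groups = {
        g: GroupSpec(ns[g], dict(GROUP_BP[g]), dict(GROUP_WR[g])) for g in ns
    }
    return CohortSpec(groups=groups, seed=11, n_blocks=4)
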