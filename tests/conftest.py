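from datetime import date

import pytest

from cfrecruit import randomization as rz
from cfrecruit import synth_population as sp

STUDY_START = date(2015, 1, 1)
STUDY_END = date(2016, 1, 1)


@pytest.fixture(scope="session")
def small_population():
    """One-center pool, both blocks, fixed seed."""
    cfg = sp.PopulationConfig(n_centers=1, adults_per_center=80, pediatrics_per_center=20, seed=11)
    return sp.generate_population(cfg)


@pytest.fixture(scope="session")
def multicenter_population():
    """Nine centers at the published eligible-pool scale (~696 adults, ~154 children)."""
    cfg = sp.PopulationConfig(seed=7)
    return sp.generate_population(cfg)


def make_threshold_states(patients, letters, target_total, consent_rate=0.53, show_rate=0.90,
                          study_start=STUDY_START, study_end=STUDY_END):
    """Initial per-block thresholds from the planning arithmetic."""
    pool_sizes = letters.groupby("block_key").size()
    total = int(pool_sizes.sum())
    states = {}
    for bk, pool in pool_sizes.items():
        block_target = target_total * pool / total
        dec = rz.required_threshold(int(pool), block_target, consent_rate, show_rate)
        states[bk] = rz.ThresholdState(
            block_key=bk, k=dec.k, effective_from=study_start,
            consent_rate_estimate=consent_rate, show_rate_estimate=show_rate,
            pool_size=int(pool), target_total=int(round(block_target)),
            target_remaining=int(round(block_target)),
            study_start=study_start, study_end=study_end,
        )
    return states
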