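import numpy as np
import pytest

import boldcsf as bc
from boldcsf.pipeline import build_cohort_table, extract_all
from boldcsf.stats import longitudinal_change


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (120 sessions) run through the full
    extraction + coupling pipeline; shared across tests that only read it."""
    cfg = bc.SimulationConfig(n_subjects=60, sessions_per_subject=2, seed=42)
    cohort = bc.simulate_cohort(cfg)
    signals = extract_all(cohort.sessions)
    table, ccfs = build_cohort_table(cohort, signals)
    table = table.merge(
        cohort.truth[["session_id", "gain", "arousal_level"]], on="session_id"
    )
    table["d_suvr"] = longitudinal_change(table["suvr_base"], table["suvr_fu"])
    table["d_mmse"] = longitudinal_change(table["mmse_base"], table["mmse_fu"])
    return {"config": cfg, "cohort": cohort, "signals": signals, "table": table, "ccfs": ccfs}


def cosine_session(tr_seconds=3.0, duration=420.0, period=20.0, delay=3.0, dt=0.5):
    """G = cos(2πt/period) with F its delayed negative derivative, both
    block-averaged from the generation grid to TR."""
    from boldcsf.synthetic import block_average, simulate_csf_inflow

    t = np.arange(0, duration, dt)
    g0 = np.cos(2 * np.pi * t / period)
    f0, _ = simulate_csf_inflow(g0, dt, delay, gain=1.0)
    factor = int(round(tr_seconds / dt))
    return block_average(g0, factor), block_average(f0, factor)
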