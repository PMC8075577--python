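"""Shared fixtures: handcrafted sessions and reusable simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import choicelat as cl
from choicelat.trial_data import OMISSION_LATENCY_S, TrialRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_session(
    rat_id: str,
    session_index: int,
    chosen=("saccharin",) * 8,
    sampling_latencies=(5.0, 6.0, 5.5, 6.5),
    choice_latencies=(4.0,) * 8,
    first="cocaine",
) -> list[TrialRecord]:
    """Build one valid 12-trial session; latency 300 marks an omission."""
    second = "saccharin" if first == "cocaine" else "cocaine"
    records = []
    for i, (option, lat) in enumerate(
        zip((first, second, first, second), sampling_latencies), start=1
    ):
        omission = lat == OMISSION_LATENCY_S
        records.append(
            TrialRecord(
                rat_id, session_index, i, "sampling", option,
                "none" if omission else option, lat, omission,
            )
        )
    for i, (ch, lat) in enumerate(zip(chosen, choice_latencies), start=5):
        omission = ch == "none"
        records.append(
            TrialRecord(
                rat_id, session_index, i, "choice", "both", ch,
                OMISSION_LATENCY_S if omission else lat, omission,
            )
        )
    return records


@pytest.fixture(scope="session")
def balanced_scm_summaries():
    """SCM cohort with 19 rats per archetype, 3-session analysis window."""
    config = cl.CohortConfig(
        regime="SCM", n_rats={"SP": 19, "IND": 19, "CP": 19},
        n_sessions=5, seed=11,
    )
    records = cl.simulate_cohort(config)
    return cl.summarize_cohort(cl.select_analysis_window(records, 3))


@pytest.fixture(scope="session")
def mixture_scm_summaries():
    """SCM cohort spanning the preference spectrum (n=60)."""
    config = cl.CohortConfig(
        regime="SCM", n_rats={"SP": 30, "IND": 15, "CP": 15},
        n_sessions=5, seed=5,
    )
    records = cl.simulate_cohort(config)
    return cl.summarize_cohort(cl.select_analysis_window(records, 3))


@pytest.fixture(scope="session")
def small_cohort_records():
    """Small mixed SCM cohort used by I/O and structural tests."""
    config = cl.CohortConfig(
        regime="SCM", n_rats={"SP": 4, "IND": 3, "CP": 3},
        n_sessions=4, seed=2,
    )
    return cl.simulate_cohort(config)
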