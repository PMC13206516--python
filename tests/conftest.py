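"""Shared fixtures.

The expensive multi-seed simulations (direction recovery and the null
comparison) are session-scoped so the property suites and the
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from popscore.nirs import summarize_session
from popscore.score import score_cohort
from popscore.synthetic import (
    default_config,
    generate_cohort,
    generate_null_cohort,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort30(config):
    """The packaged 30-neonate synthetic fixture: 6 cases, 24 controls, seed 42."""
    return generate_cohort(config, 6, 24, seed=42)


def _group_score_medians(cohort):
    """Median POP-Score per group after running summarize + score."""
    summaries = [summarize_session(s) for s in cohort.sessions]
    scores, unjoinable = score_cohort(summaries, cohort.records)
    assert not unjoinable
    groups = dict(zip(cohort.latent["id"], cohort.latent["group"]))
    case = [r.score for r in scores if groups[r.neonate_id] == "case"]
    ctrl = [r.score for r in scores if groups[r.neonate_id] == "control"]
    return float(np.median(case)), float(np.median(ctrl))


@pytest.fixture(scope="session")
def direction_medians(config):
    """(case median, control median) for 20 seeded 200/200 cohorts."""
    return [
        _group_score_medians(generate_cohort(config, 200, 200, seed=seed))
        for seed in range(20)
    ]


@pytest.fixture(scope="session")
def null_medians(config):
    """Same comparison under the null generator, 50 seeds at 200/200."""
    return [
        _group_score_medians(generate_null_cohort(config, 200, 200, seed=seed))
        for seed in range(50)
    ]


@pytest.fixture(scope="session")
def calibration_cohorts(config):
    """One large cohort (500 per group, seed 7) for calibration checks."""
    return generate_cohort(config, 500, 500, seed=7)
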