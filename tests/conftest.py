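"""Shared fixtures: small hand-built cohorts and generated presets."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from ergscreen.synthetic_data import make_fixture
from ergscreen.waveform_io import (
    Cohort,
    ERGTrace,
    EXPECTED_TRIALS,
    MouseSession,
    WILDTYPE_STRAIN,
)


def make_trace(
    mouse_id: str,
    eye: str = "L",
    condition: str = "scotopic",
    trial: int = 1,
    samples: np.ndarray | None = None,
    rate: float = 2000.0,
) -> ERGTrace:
    """A minimal valid trace: zeros over the full required epoch."""
    n_pre = {"scotopic": 40, "photopic": 20}[condition]
    post_ms = {"scotopic": 5000.0, "photopic": 100.0}[condition]
    n = n_pre + int(round(post_ms / 1000.0 * rate)) + 1
    if samples is None:
        samples = np.zeros(n)
    return ERGTrace(
        mouse_id=mouse_id,
        eye=eye,
        condition=condition,
        trial=trial,
        samples=samples,
        sample_rate_hz=rate,
        t0_offset_s=n_pre / rate,
    )


def make_session(
    mouse_id: str,
    strain_id: str = WILDTYPE_STRAIN,
    sex: str = "M",
    day: date = date(2020, 3, 2),
    zygosity: str | None = None,
) -> MouseSession:
    if zygosity is None:
        zygosity = "wildtype" if strain_id == WILDTYPE_STRAIN else "homozygous"
    return MouseSession(
        mouse_id=mouse_id,
        strain_id=strain_id,
        zygosity=zygosity,
        sex=sex,
        test_date=day,
        batch_id="b0",
    )


def full_grid_traces(mouse_id: str, rng: np.random.Generator | None = None) -> list[ERGTrace]:
    """A complete trace grid for one mouse (both eyes, both conditions)."""
    traces = []
    for condition in ("scotopic", "photopic"):
        for eye in ("L", "R"):
            for trial in range(1, EXPECTED_TRIALS[condition] + 1):
                tr = make_trace(mouse_id, eye, condition, trial)
                if rng is not None:
                    tr.samples = tr.samples + rng.normal(0, 1.0, len(tr.samples))
                traces.append(tr)
    return traces


@pytest.fixture
def two_mouse_cohort() -> Cohort:
    rng = np.random.default_rng(42)
    sessions = [make_session("m1"), make_session("m2", strain_id="strainX")]
    traces = full_grid_traces("m1", rng) + full_grid_traces("m2", rng)
    return Cohort(sessions=sessions, traces=traces)


@pytest.fixture(scope="session")
def tiny_clean():
    return make_fixture("tiny-clean")


@pytest.fixture(scope="session")
def one_hit():
    return make_fixture("one-hit")


@pytest.fixture(scope="session")
def dimorphic():
    return make_fixture("dimorphic")


# Small test cohorts legitimately trip the unstable-quantile and
# all-ones-fallback warnings; they are filtered in pyproject.toml.
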