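"""Shared fixtures: small synthetic recordings built on uniform grids."""

import numpy as np
import pytest

from kcindex import CohortSpec, LimbRecording, SubjectRecording, LIMB_IDS


def make_subject(
    duration=20.0,
    rate=150.0,
    signal_fn=None,
    offsets=None,
    subject_id="S1",
    gm_label=None,
):
    """Build a subject whose limbs evaluate ``signal_fn(limb_id, t) -> (n, 3)``.

    ``offsets`` maps limb_id -> clock offset in seconds added to that limb's
    timestamps (device-local clocks). Default signal: independent smooth
    sinusoids per limb so every feature is well defined.
    """
    if signal_fn is None:
        def signal_fn(limb_id, t):
            k = LIMB_IDS.index(limb_id) + 1
            return np.column_stack(
                [np.sin(2 * np.pi * 0.7 * k * t + a) for a in (0.0, 1.0, 2.0)]
            )
    offsets = offsets or {}
    n = int(round(duration * rate)) + 1
    limbs = {}
    for limb_id in LIMB_IDS:
        t = offsets.get(limb_id, 0.0) + np.arange(n) / rate
        limbs[limb_id] = LimbRecording(
            limb_id=limb_id, timestamps=t, accel=signal_fn(limb_id, t), nominal_rate=rate
        )
    return SubjectRecording(subject_id=subject_id, limbs=limbs, gm_label=gm_label)


@pytest.fixture
def uniform_subject():
    return make_subject()


@pytest.fixture(scope="session")
def short_cohort_spec():
    """A small, quick cohort specification used by pipeline-level tests."""
    return CohortSpec(
        n_per_group={"N": 3, "PR": 2, "CS": 1}, duration_s=120.0, seed=11
    )


@pytest.fixture(autouse=True)
def _quiet_short_record_warning():
    """Short fixtures trip the <3/cutoff duration warning; keep test output clean."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*shorter than 3/cutoff.*", category=UserWarning
        )
        yield
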