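"""Shared fixtures: layouts, schedules, and (costly) synthetic sessions.

Session-scoped fixtures hold the expensive synthetic datasets so the
decoder and classifier suites share one generation pass per condition.
"""

import numpy as np
import pytest

from mtpbci import fbcsp, mtp, paradigm, synthgen

#: reduced sensorimotor montage used where full-montage cost is not the point
MONTAGE8 = ("FC3", "FC4", "C3", "C4", "Cz", "CP3", "CP4", "CPz")


@pytest.fixture(scope="session")
def layout():
    return paradigm.TargetLayout.default()


@pytest.fixture(scope="session")
def offline_schedule(layout):
    return paradigm.build_offline_schedule(layout, n_runs=6, seed=0)


@pytest.fixture(scope="session")
def online_schedule(layout):
    return paradigm.build_online_schedule(layout, n_runs=2, seed=0)


@pytest.fixture(scope="session")
def noiseless_session(layout, offline_schedule):
    """Velocity-encoded session with all noise sources off."""
    noise = synthgen.NoiseSpec(
        channel_scale=0.0, common_mode_scale=0.0, line_amplitude=0.0
    )
    rec, kin = synthgen.synthesize_mtp_session(
        offline_schedule, layout, noise=noise, seed=0
    )
    return rec, kin


@pytest.fixture(scope="session")
def noiseless_dataset(layout, offline_schedule, noiseless_session):
    rec, kin = noiseless_session
    return mtp.prepare_dataset(
        rec, offline_schedule, kin, layout, qc=False, window_step_samples=3
    )


@pytest.fixture(scope="session")
def default_session(layout, offline_schedule):
    """Velocity-encoded session at the default (realistic) noise level."""
    rec, kin = synthgen.synthesize_mtp_session(offline_schedule, layout, seed=0)
    return rec, kin


@pytest.fixture(scope="session")
def default_dataset(layout, offline_schedule, default_session):
    rec, kin = default_session
    return mtp.prepare_dataset(
        rec, offline_schedule, kin, layout, qc=False, window_step_samples=3
    )


#: reduced hyperparameter grid keeping nested-CV suites tractable
SMALL_PLAN_KW = dict(
    n_pairs_grid=(1, 2),
    n_levels_grid=(4, 8),
    k_grid=(4, 8),
    gamma_grid=(0.1, 0.5),
)


@pytest.fixture(scope="session")
def fbcsp_fixture_results(layout):
    """Nested-CV results on the contralateral mu-suppression fixture.

    Two seeds of a 6-run session (36 trials/class, 2x mu variance ratio
    on C3/C4); shared by the classifier suite and the end-to-end
    acceptance checks.
    """
    out = []
    for seed in (0, 1):
        sched = paradigm.build_offline_schedule(layout, n_runs=6, seed=seed)
        rec, trials = synthgen.synthesize_class_session(sched, seed=seed)
        ds = fbcsp.build_trial_dataset(rec, trials)
        plan = fbcsp.NestedCVPlan.single_session(**SMALL_PLAN_KW)
        out.append((ds, fbcsp.nested_cv(ds, plan)))
    return out
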