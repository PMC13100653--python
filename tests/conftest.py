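import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from idhrisk import SessionRecord, generate_cohort, load_packaged_config

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_session(
    rbv=None,
    vitals_times=(0, 30, 60, 90, 120, 150, 180, 210, 240),
    sbp=None,
    duration=240,
    patient_id="P1",
    session_id="S1",
    session_order=1,
    ht0=33.0,
):
    """Construct a SessionRecord from an RBV series (hematocrit back-computed)."""
    if rbv is None:
        rbv = np.full(duration + 1, 100.0)
    rbv = np.asarray(rbv, dtype=float)
    duration = rbv.size - 1
    ht = ht0 * 100.0 / rbv
    times = np.asarray(vitals_times, dtype=int)
    times = times[times <= duration]
    if sbp is None:
        sbp = np.full(times.size, 130.0)
    vit = pd.DataFrame(
        {
            "t_min": times,
            "sbp": np.asarray(sbp, dtype=float),
            "dbp": 75.0,
            "hr": 72.0,
        }
    )
    return SessionRecord(
        patient_id=patient_id,
        session_id=session_id,
        session_order=session_order,
        duration_min=duration,
        t_min=np.arange(duration + 1),
        hematocrit_pct=ht,
        rbv_pct=rbv,
        vitals=vit,
    )


@pytest.fixture(scope="session")
def small_continuous_cohort():
    """Reduced-scale continuous-mode cohort for fast model tests."""
    from dataclasses import replace

    cfg, eff = load_packaged_config("paper_continuous")
    cfg = replace(cfg, n_patients=20, sessions_per_patient=6)
    return generate_cohort(cfg, eff, seed=7)


@pytest.fixture(scope="session")
def small_archetype_cohort():
    from dataclasses import replace

    cfg, eff = load_packaged_config("paper_archetype")
    cfg = replace(cfg, n_patients=12, sessions_per_patient=5)
    return generate_cohort(cfg, eff, seed=11)
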