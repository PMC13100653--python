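"""CSV interchange for cohorts and prediction rows.

A cohort on disk is four UTF-8 CSVs with header rows:

- ``sessions.csv``: patient_id, session_id, session_order, duration_min
- ``machine.csv``:  session_id, t_min, hematocrit_pct
- ``vitals.csv``:   session_id, t_min, sbp, dbp, hr
- ``truth.csv``:    (generated cohorts only) ground truth per session

Missing values are empty fields.  RBV is re-derived from hematocrit on read.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SessionRecord, compute_rbv


def write_cohort(sessions: Sequence[SessionRecord], outdir: str,
                 truth: Optional[pd.DataFrame] = None) -> None:
    os.makedirs(outdir, exist_ok=True)
    meta = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "session_id": s.session_id,
                "session_order": s.session_order,
                "duration_min": s.duration_min,
            }
            for s in sessions
        ]
    )
    machine = pd.concat(
        [
            pd.DataFrame(
                {
                    "session_id": s.session_id,
                    "t_min": s.t_min,
                    "hematocrit_pct": np.round(s.hematocrit_pct, 4),
                }
            )
            for s in sessions
        ],
        ignore_index=True,
    )
    vitals = pd.concat(
        [s.vitals.assign(session_id=s.session_id)[["session_id", "t_min", "sbp", "dbp", "hr"]]
         for s in sessions],
        ignore_index=True,
    )
    meta.to_csv(os.path.join(outdir, "sessions.csv"), index=False)
    machine.to_csv(os.path.join(outdir, "machine.csv"), index=False)
    vitals.to_csv(os.path.join(outdir, "vitals.csv"), index=False)
    if truth is not None:
        truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)


def read_cohort(indir: str, rbv_baseline: str = "mean0_2") -> List[SessionRecord]:
    meta = pd.read_csv(os.path.join(indir, "sessions.csv"))
    machine = pd.read_csv(os.path.join(indir, "machine.csv"))
    vitals = pd.read_csv(os.path.join(indir, "vitals.csv"))
    sessions = []
    for _, r in meta.iterrows():
        sid = r["session_id"]
        mc = machine[machine["session_id"] == sid].sort_values("t_min")
        vt = vitals[vitals["session_id"] == sid].sort_values("t_min")
        sessions.append(
            SessionRecord.from_channels(
                patient_id=r["patient_id"],
                session_id=sid,
                session_order=int(r["session_order"]),
                t_min=mc["t_min"].to_numpy(dtype=int),
                hematocrit_pct=mc["hematocrit_pct"].to_numpy(dtype=float),
                vitals=vt[["t_min", "sbp", "dbp", "hr"]].reset_index(drop=True),
                rbv_baseline=rbv_baseline,
            )
        )
    return sessions


def sessions_meta(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """Metadata frame (patient_id, session_id, session_order) for splitting."""
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "session_id": s.session_id,
                "session_order": s.session_order,
            }
            for s in sessions
        ]
    )


def write_rows(rows: pd.DataFrame, path: str) -> None:
    rows.to_csv(path, index=False)


def read_rows(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
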