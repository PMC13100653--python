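"""Core dialysis-session time series: containers, RBV, IDH labels, prediction rows.

A hemodialysis session is observed on two clocks: the machine reports
hematocrit every minute, while blood pressure and heart rate are measured
intermittently (every ~30 min).  Relative blood volume (RBV) is derived from
hematocrit as ``100 * Ht(0) / Ht(t)`` — hemoconcentration during
ultrafiltration raises hematocrit and lowers RBV.  Intradialytic hypotension
(IDH) is flagged at a vitals measurement when systolic blood pressure falls
below 90 mmHg with at least a 20 mmHg drop from the session's first reading.

``build_rows`` flattens a session into one modelling row per vitals entry,
either labelled with the concurrent IDH flag or with the occurrence of IDH in
a near-future horizon window (default ``(t+10, t+60]`` minutes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Systolic pressure ceiling for an IDH flag (mmHg).
IDH_SBP_LIMIT = 90.0
#: Minimum drop from the session's first systolic reading (mmHg).
IDH_MIN_DROP = 20.0

ROW_COLUMNS = [
    "patient_id",
    "session_id",
    "t_min",
    "rbv_pct",
    "delta_rbv",
    "drbv_dt",
    "sbp",
    "delta_sbp",
    "hr",
    "below_threshold",
    "label",
    "label_mode",
]


class ValidationError(ValueError):
    """Raised when a session or channel violates a structural invariant."""


def compute_rbv(
    hematocrit_pct: Sequence[float],
    baseline: Literal["mean0_2", "first"] = "mean0_2",
) -> np.ndarray:
    """Relative blood volume (%) from a per-minute hematocrit series.

    RBV(t) = 100 * Ht(0) / Ht(t).  ``baseline`` selects how Ht(0) is formed:
    ``"mean0_2"`` (default) averages the first three minutes, which is robust
    to sensor settling noise; ``"first"`` uses the first reading alone, in
    which case RBV(0) is exactly 100.
    """
    ht = np.asarray(hematocrit_pct, dtype=float)
    if ht.size == 0:
        raise ValidationError("hematocrit series is empty")
    bad = np.where(~((ht > 0.0) & (ht < 100.0)))[0]
    if bad.size:
        raise ValidationError(
            f"hematocrit out of (0, 100) at index {bad[0]}: {ht[bad[0]]!r}"
        )
    if baseline == "mean0_2":
        ht0 = float(ht[: min(3, ht.size)].mean())
    elif baseline == "first":
        ht0 = float(ht[0])
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return 100.0 * ht0 / ht


@dataclass
class IdhLabelSet:
    """Per-vitals-entry IDH flags plus session-level summaries."""

    flags: np.ndarray  # bool, aligned with the vitals table rows
    any_idh: bool
    first_event_time_min: Optional[float]

    @property
    def n_events(self) -> int:
        return int(self.flags.sum())


def label_idh(vitals: pd.DataFrame, baseline_sbp: Optional[float] = None) -> IdhLabelSet:
    """Flag IDH at each vitals entry.

    An entry is flagged iff ``sbp < 90`` and ``baseline_sbp - sbp >= 20``;
    the baseline is the first recorded systolic pressure of the session
    (pre-dialysis readings are unaffected by the treatment itself).
    """
    if vitals is None or len(vitals) == 0:
        raise ValidationError("vitals table is empty; cannot label IDH")
    sbp = vitals["sbp"].to_numpy(dtype=float)
    if baseline_sbp is None:
        baseline_sbp = float(sbp[np.argmin(vitals["t_min"].to_numpy())])
    flags = (sbp < IDH_SBP_LIMIT) & ((baseline_sbp - sbp) >= IDH_MIN_DROP)
    any_idh = bool(flags.any())
    first = None
    if any_idh:
        first = float(vitals["t_min"].to_numpy(dtype=float)[flags].min())
    return IdhLabelSet(flags=flags, any_idh=any_idh, first_event_time_min=first)


@dataclass
class SessionRecord:
    """One dialysis session: per-minute machine channel + intermittent vitals.

    The machine channel lives on an integer minute grid ``t = 0..duration_min``
    with hematocrit (%) and derived RBV (%).  ``vitals`` is a DataFrame with
    columns ``t_min, sbp, dbp, hr`` whose times lie on the minute grid.
    """

    patient_id: str
    session_id: str
    session_order: int
    duration_min: int
    t_min: np.ndarray
    hematocrit_pct: np.ndarray
    rbv_pct: np.ndarray
    vitals: pd.DataFrame
    rbv_baseline: str = "mean0_2"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=int)
        self.hematocrit_pct = np.asarray(self.hematocrit_pct, dtype=float)
        self.rbv_pct = np.asarray(self.rbv_pct, dtype=float)

    @classmethod
    def from_channels(
        cls,
        patient_id: str,
        session_id: str,
        session_order: int,
        t_min: Sequence[int],
        hematocrit_pct: Sequence[float],
        vitals: pd.DataFrame,
        rbv_baseline: str = "mean0_2",
    ) -> "SessionRecord":
        t = np.asarray(t_min, dtype=int)
        rbv = compute_rbv(hematocrit_pct, baseline=rbv_baseline)  # type: ignore[arg-type]
        rec = cls(
            patient_id=str(patient_id),
            session_id=str(session_id),
            session_order=int(session_order),
            duration_min=int(t[-1]) if t.size else 0,
            t_min=t,
            hematocrit_pct=np.asarray(hematocrit_pct, dtype=float),
            rbv_pct=rbv,
            vitals=vitals.reset_index(drop=True),
            rbv_baseline=rbv_baseline,
        )
        rec.validate()
        return rec

    def validate(self) -> None:
        t = self.t_min
        if t.size == 0:
            raise ValidationError(f"{self.session_id}: empty machine channel")
        if t[0] != 0 or not np.all(np.diff(t) == 1):
            raise ValidationError(
                f"{self.session_id}: minute grid must start at 0 with step 1"
            )
        if self.session_order < 1:
            raise ValidationError(f"{self.session_id}: session_order must be >= 1")
        if not np.all((self.hematocrit_pct > 0) & (self.hematocrit_pct < 100)):
            raise ValidationError(f"{self.session_id}: hematocrit out of (0, 100)")
        # rbv(0) = 100 exactly under baseline="first"; within 1% otherwise
        # (the averaged baseline trades that exactness for noise robustness).
        tol = 1e-9 if self.rbv_baseline == "first" else 1.0
        if abs(self.rbv_pct[0] - 100.0) > tol:
            raise ValidationError(
                f"{self.session_id}: rbv(0) = {self.rbv_pct[0]:.3f}, expected 100"
            )
        vt = self.vitals["t_min"].to_numpy(dtype=float)
        if len(vt) == 0:
            raise ValidationError(f"{self.session_id}: no vitals entries")
        if not np.all(np.isin(vt, t)):
            raise ValidationError(f"{self.session_id}: vitals times off the minute grid")
        if vt.min() > 5:
            raise ValidationError(
                f"{self.session_id}: no vitals entry at or before t=5 (baseline)"
            )

    @property
    def baseline_sbp(self) -> float:
        v = self.vitals
        return float(v["sbp"].to_numpy(dtype=float)[np.argmin(v["t_min"].to_numpy())])

    def labels(self) -> IdhLabelSet:
        return label_idh(self.vitals, self.baseline_sbp)

    def rbv_at(self, t: float) -> float:
        i = int(round(t))
        if i < 0 or i >= self.t_min.size:
            raise ValidationError(f"{self.session_id}: t={t} outside the minute grid")
        return float(self.rbv_pct[i])


def compute_drbv_dt(
    rbv_series: Sequence[float], t: int, window_min: int = 10
) -> float:
    """Trailing least-squares RBV slope (%/min) over ``[t - window_min, t]``.

    Negative while blood volume is falling.  Returns NaN (undefined-feature
    marker) when fewer than two in-window points exist; callers drop such rows.
    """
    rbv = np.asarray(rbv_series, dtype=float)
    if t < window_min:
        return float("nan")
    lo = max(0, t - window_min)
    tt = np.arange(lo, t + 1, dtype=float)
    yy = rbv[lo : t + 1]
    if tt.size < 2:
        return float("nan")
    slope = np.polyfit(tt, yy, 1)[0]
    return float(slope)


def build_rows(
    session: SessionRecord,
    labels: Optional[IdhLabelSet] = None,
    mode: Literal["concurrent", "horizon"] = "concurrent",
    horizon_min: tuple[float, float] = (10.0, 60.0),
    threshold_curve=None,
    drbv_window_min: int = 10,
    include_ongoing: bool = False,
) -> pd.DataFrame:
    """Assemble one prediction row per eligible vitals entry.

    ``mode="concurrent"`` labels each row with that entry's own IDH flag;
    ``mode="horizon"`` labels a row at time t with 1 iff any flagged entry
    falls in ``(t + horizon_min[0], t + horizon_min[1]]`` — the entry at t
    itself never contributes.  Windows running past the session end are
    truncated (counted, not an error); rows whose truncated window is empty
    are dropped.  In horizon mode rows where IDH is already ongoing at t are
    excluded unless ``include_ongoing``.  ``threshold_curve`` (a
    :class:`idhrisk.threshold.ThresholdCurve` or any object with a
    ``below(rbv, t)`` method) fills the ``below_threshold`` feature.
    """
    if labels is None:
        labels = session.labels()
    vit = session.vitals.reset_index(drop=True)
    times = vit["t_min"].to_numpy(dtype=float)
    sbp = vit["sbp"].to_numpy(dtype=float)
    hr = vit["hr"].to_numpy(dtype=float)
    flags = np.asarray(labels.flags, dtype=bool)
    base_sbp = session.baseline_sbp
    event_times = times[flags]
    lo_h, hi_h = float(horizon_min[0]), float(horizon_min[1])

    n_truncated = 0
    n_dropped_undefined = 0
    n_dropped_ongoing = 0
    rows = []
    for i, t in enumerate(times):
        rbv_t = session.rbv_at(t)
        slope = compute_drbv_dt(session.rbv_pct, int(round(t)), drbv_window_min)
        if not np.isfinite(slope):
            n_dropped_undefined += 1
            continue
        if mode == "horizon":
            if flags[i] and not include_ongoing:
                n_dropped_ongoing += 1
                continue
            win_lo, win_hi = t + lo_h, t + hi_h
            if win_hi > session.duration_min:
                n_truncated += 1
                win_hi = float(session.duration_min)
            if win_hi <= win_lo:
                continue  # truncated window is empty
            label = int(np.any((event_times > win_lo) & (event_times <= win_hi)))
        else:
            label = int(flags[i])
        below = np.nan
        if threshold_curve is not None:
            below = float(threshold_curve.below(rbv_t, t))
        rows.append(
            {
                "patient_id": session.patient_id,
                "session_id": session.session_id,
                "t_min": t,
                "rbv_pct": rbv_t,
                "delta_rbv": 100.0 - rbv_t,
                "drbv_dt": slope,
                "sbp": sbp[i],
                "delta_sbp": base_sbp - sbp[i],
                "hr": hr[i],
                "below_threshold": below,
                "label": label,
                "label_mode": mode,
            }
        )
    if n_truncated:
        logger.debug(
            "%s: %d horizon windows truncated at session end",
            session.session_id,
            n_truncated,
        )
    if n_dropped_undefined:
        logger.debug(
            "%s: %d rows dropped (dRBV/dt undefined)",
            session.session_id,
            n_dropped_undefined,
        )
    if n_dropped_ongoing:
        logger.debug(
            "%s: %d rows dropped (IDH ongoing at t)",
            session.session_id,
            n_dropped_ongoing,
        )
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


def build_rows_cohort(
    sessions: Sequence[SessionRecord],
    mode: Literal["concurrent", "horizon"] = "concurrent",
    **kwargs,
) -> pd.DataFrame:
    """Concatenate :func:`build_rows` over a cohort of sessions."""
    frames = [f for f in (build_rows(s, mode=mode, **kwargs) for s in sessions) if len(f)]
    if not frames:
        return pd.DataFrame(columns=ROW_COLUMNS)
    return pd.concat(frames, ignore_index=True)
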