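"""Time-dependent RBV threshold separating high- from low-risk trajectories.

At each grid time the RBV values of sessions still running are pooled by risk
group and the cutoff maximizing the Youden index (sensitivity + specificity
− 1, classifying "RBV below cutoff → high-risk") is recorded.  The raw
per-time cutoffs are LOESS-smoothed and a pointwise percentile bootstrap
(resampling sessions within risk group) provides a confidence band.  The
resulting curve yields a below-threshold indicator used as a binary
covariate in the risk models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


def youden_threshold_at_time(
    values_high: Sequence[float], values_low: Sequence[float]
) -> Tuple[float, float]:
    """Best RBV cutoff at one timepoint and its Youden index J.

    Candidate cutoffs are the midpoints between adjacent distinct pooled
    values; "below cutoff" classifies as high-risk.  Among equally maximizing
    gaps the lowest gap's midpoint is returned (J is constant on each open
    gap between adjacent distinct values, so the midpoint represents the
    whole maximizing interval).
    """
    hi = np.asarray(values_high, dtype=float)
    lo = np.asarray(values_low, dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both risk groups must be non-empty at this timepoint")
    pooled = np.unique(np.concatenate([hi, lo]))
    if pooled.size < 2:
        return float(pooled[0]), 0.0
    cuts = 0.5 * (pooled[:-1] + pooled[1:])
    sens = np.array([(hi < c).mean() for c in cuts])
    spec = np.array([(lo >= c).mean() for c in cuts])
    J = sens + spec - 1.0
    best = int(np.argmax(J))  # argmax returns the first (lowest) maximizing gap
    if J[best] < 0.0:
        # groups are inverted at this time: never classifying "below" beats
        # every interior cutoff, so return the no-positive boundary with J=0
        return float(pooled[0]), 0.0
    return float(cuts[best]), float(J[best])


def derive_raw_threshold(
    sessions: Sequence,
    risk_by_session: Dict[str, str],
    grid_step_min: int = 5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-grid-time Youden cutoffs between high- and low-risk sessions.

    Returns ``(t_grid, raw_threshold, J)`` restricted to grid times where both
    groups still have running sessions; other grid points are skipped.
    """
    highs = [s for s in sessions if risk_by_session[s.session_id] == "high"]
    lows = [s for s in sessions if risk_by_session[s.session_id] == "low"]
    if not highs or not lows:
        raise ValueError("need at least one session in each risk group")
    t_max = max(s.duration_min for s in sessions)
    ts, raws, js = [], [], []
    skipped = 0
    for t in range(0, t_max + 1, grid_step_min):
        vh = [s.rbv_pct[t] for s in highs if t <= s.duration_min]
        vl = [s.rbv_pct[t] for s in lows if t <= s.duration_min]
        if not vh or not vl:
            skipped += 1
            continue
        cut, J = youden_threshold_at_time(vh, vl)
        ts.append(float(t))
        raws.append(cut)
        js.append(J)
    if skipped:
        logger.debug("raw threshold: %d grid points skipped (empty group)", skipped)
    return np.asarray(ts), np.asarray(raws), np.asarray(js)


def loess_smooth(x: Sequence[float], y: Sequence[float], span: float = 0.3) -> np.ndarray:
    """LOESS fit (local linear, tricube weights) evaluated at each ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("loess_smooth needs at least 4 points")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    out = lowess(y, x, frac=span, it=0, xvals=x)
    return np.asarray(out, dtype=float)


@dataclass
class ThresholdCurve:
    """Dynamic RBV threshold: raw and smoothed cutoffs with a bootstrap band."""

    t_grid: np.ndarray
    raw: np.ndarray
    smooth: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def threshold_at(self, t) -> np.ndarray:
        """Smoothed threshold, linearly interpolated (nearest value outside)."""
        return np.interp(t, self.t_grid, self.smooth)

    def below(self, rbv_value: float, t: float) -> int:
        """1 iff ``rbv_value`` lies strictly below the smoothed threshold."""
        return int(float(rbv_value) < float(self.threshold_at(t)))

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_min": self.t_grid,
                "raw": self.raw,
                "smooth": self.smooth,
                "ci_low": self.ci_low if self.ci_low is not None else np.nan,
                "ci_high": self.ci_high if self.ci_high is not None else np.nan,
            }
        )


def derive_threshold_curve(
    sessions: Sequence,
    risk_by_session: Dict[str, str],
    grid_step_min: int = 5,
    span: float = 0.3,
    bootstrap_B: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> ThresholdCurve:
    """Raw Youden cutoffs → LOESS smooth → optional bootstrap band."""
    ts, raw, _ = derive_raw_threshold(sessions, risk_by_session, grid_step_min)
    smooth = loess_smooth(ts, raw, span)
    ci_lo = ci_hi = None
    if bootstrap_B:
        ci_lo, ci_hi = bootstrap_threshold_ci(
            sessions, risk_by_session, B=bootstrap_B, span=span,
            grid_step_min=grid_step_min, level=level, seed=seed, base_grid=ts,
        )
    return ThresholdCurve(
        t_grid=ts, raw=raw, smooth=smooth, ci_low=ci_lo, ci_high=ci_hi,
        params={"span": span, "B": bootstrap_B, "seed": seed, "grid_step": grid_step_min},
    )


def bootstrap_threshold_ci(
    sessions: Sequence,
    risk_by_session: Dict[str, str],
    B: int = 200,
    span: float = 0.3,
    grid_step_min: int = 5,
    level: float = 0.95,
    seed: int = 0,
    base_grid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile bootstrap band for the smoothed threshold.

    Sessions are resampled with replacement within each risk group; the raw
    and smoothed threshold are re-derived per replicate and pointwise
    ``(1±level)/2`` percentiles are taken on the base grid.  Replicate grid
    points absent (because the replicate's groups do not cover them) enter
    as NaN and are ignored by the percentile.
    """
    rng = np.random.default_rng(seed)
    highs = [s for s in sessions if risk_by_session[s.session_id] == "high"]
    lows = [s for s in sessions if risk_by_session[s.session_id] == "low"]
    if base_grid is None:
        base_grid, _, _ = derive_raw_threshold(sessions, risk_by_session, grid_step_min)[0:3]
    base_grid = np.asarray(base_grid, dtype=float)
    reps = np.full((B, base_grid.size), np.nan)
    for b in range(B):
        rs = [highs[i] for i in rng.integers(0, len(highs), len(highs))]
        rs += [lows[i] for i in rng.integers(0, len(lows), len(lows))]
        risk = {}
        boot_sessions = []
        for idx, s in enumerate(rs):
            # duplicate draws get distinct ids so the risk map stays a partition
            clone_id = f"{s.session_id}#b{idx}"
            boot_sessions.append(_Renamed(s, clone_id))
            risk[clone_id] = risk_by_session[s.session_id]
        ts, raw, _ = derive_raw_threshold(boot_sessions, risk, grid_step_min)
        if ts.size < 4:
            continue
        sm = loess_smooth(ts, raw, span)
        reps[b] = np.interp(base_grid, ts, sm, left=np.nan, right=np.nan)
    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        ci_lo = np.nanpercentile(reps, 100 * alpha, axis=0)
        ci_hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    return ci_lo, ci_hi


class _Renamed:
    """Lightweight session view with a replacement id (bootstrap clones)."""

    __slots__ = ("_s", "session_id")

    def __init__(self, session, session_id: str):
        self._s = session
        self.session_id = session_id

    def __getattr__(self, name):
        return getattr(self._s, name)
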