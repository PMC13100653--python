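"""Validation splits, discrimination metrics and the descriptive analyses.

Two split schemes mirror the two deployment scenarios: *patient-wise*
(whole patients held out — the model meets entirely new patients, so only
fixed effects can be used) and *session-wise* (each patient's later sessions
held out — the patient-specific intercept learned from earlier sessions is
available).  Discrimination is summarised by ROC AUC and the Youden
operating point (sensitivity, specificity, NPV, PPV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

#: RBV bin edges for the incidence-by-category analysis; left-closed lower
#: edge, labelled from the best-preserved volume down.
RBV_BINS = ((95.0, np.inf), (90.0, 95.0), (85.0, 90.0), (80.0, 85.0), (-np.inf, 80.0))
RBV_BIN_LABELS = (">=95", "90-95", "85-90", "80-85", "<80")


def split_sessions(
    sessions_meta: pd.DataFrame,
    mode: str = "session",
    fraction: float = 0.7,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Partition session ids into train/test.

    ``mode="patient"``: a random partition of patients — all of a patient's
    sessions land on one side.  ``mode="session"``: chronological within
    patient — each patient's earliest ``ceil(fraction * n_i)`` sessions train,
    the rest test (emulating application to future sessions of known
    patients); a patient with a single session goes to train.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1) so both sides are non-empty")
    meta = sessions_meta[["patient_id", "session_id", "session_order"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    train: List[str] = []
    test: List[str] = []
    if mode == "patient":
        patients = np.sort(meta["patient_id"].unique())
        perm = rng.permutation(patients)
        n_train = int(math.ceil(fraction * patients.size))
        n_train = min(n_train, patients.size - 1)  # keep test non-empty
        train_pat = set(perm[:n_train])
        for _, r in meta.iterrows():
            (train if r["patient_id"] in train_pat else test).append(r["session_id"])
    elif mode == "session":
        single = 0
        for _, grp in meta.groupby("patient_id"):
            grp = grp.sort_values("session_order")
            n_i = len(grp)
            if n_i == 1:
                train.extend(grp["session_id"])
                single += 1
                continue
            n_train = min(int(math.ceil(fraction * n_i)), n_i - 1)
            train.extend(grp["session_id"].iloc[:n_train])
            test.extend(grp["session_id"].iloc[n_train:])
        if single:
            logger.debug("%d single-session patients assigned to train", single)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    if not test:
        raise ValueError("split produced an empty test side")
    return train, test


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance-probability AUC (ties count 1/2); NaN if one class absent."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, s))


def operating_point(scores: Sequence[float], labels: Sequence[int]) -> dict:
    """Youden-maximizing classification threshold and its 2x2 metrics.

    Positive iff ``score >= threshold``; the threshold maximizing
    sensitivity + specificity − 1 over the unique scores is returned (lowest
    such threshold on ties, favouring sensitivity).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    best = None
    for thr in np.unique(s):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        J = sens + spec - 1.0
        if best is None or J > best["youden_j"] + 1e-12:
            npv = tn / (tn + fn) if (tn + fn) else float("nan")
            ppv = tp / (tp + fp) if (tp + fp) else float("nan")
            best = {
                "threshold": float(thr),
                "sensitivity": sens,
                "specificity": spec,
                "npv": npv,
                "ppv": ppv,
                "youden_j": J,
                "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
            }
    return best


@dataclass
class EvaluationReport:
    """Train/test discrimination of one predictive model under one split."""

    split_mode: str
    fraction: float
    seed: int
    formula: str
    use_random_effects: bool
    auc_train: float
    auc_test: float
    operating: dict
    n_train_rows: int
    n_test_rows: int
    n_train_sessions: int
    n_test_sessions: int
    sigma_b: float

    def to_dict(self) -> dict:
        return {
            "split": {"mode": self.split_mode, "fraction": self.fraction, "seed": self.seed},
            "formula": self.formula,
            "use_random_effects": self.use_random_effects,
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "operating_point": self.operating,
            "n": {
                "train_rows": self.n_train_rows,
                "test_rows": self.n_test_rows,
                "train_sessions": self.n_train_sessions,
                "test_sessions": self.n_test_sessions,
            },
            "sigma_b": self.sigma_b,
        }


def evaluate_predictive(
    rows: pd.DataFrame,
    sessions_meta: pd.DataFrame,
    formula: str = "label ~ delta_rbv",
    split_mode: str = "session",
    fraction: float = 0.7,
    seed: int = 0,
    quad_points: int = 21,
) -> EvaluationReport:
    """Split → fit on train → score both sides → Youden operating point.

    Under a session-wise split the learned patient intercepts are used at
    test time (patients were seen in training); under a patient-wise split
    predictions are fixed-effects only.
    """
    from .glmm import MixedLogit

    train_ids, test_ids = split_sessions(sessions_meta, split_mode, fraction, seed)
    tr = rows[rows["session_id"].isin(train_ids)]
    te = rows[rows["session_id"].isin(test_ids)]
    res = MixedLogit.from_formula(formula, tr, groups="patient_id").fit(quad_points)
    use_re = split_mode == "session"
    p_tr = res.predict(tr, use_random_effects=use_re)
    p_te = res.predict(te, use_random_effects=use_re)
    op = operating_point(p_te, te["label"].to_numpy())
    return EvaluationReport(
        split_mode=split_mode,
        fraction=fraction,
        seed=seed,
        formula=formula,
        use_random_effects=use_re,
        auc_train=roc_auc(p_tr, tr["label"].to_numpy()),
        auc_test=roc_auc(p_te, te["label"].to_numpy()),
        operating=op,
        n_train_rows=len(tr),
        n_test_rows=len(te),
        n_train_sessions=len(train_ids),
        n_test_sessions=len(test_ids),
        sigma_b=res.sigma_b,
    )


# ---------------------------------------------------------------------------
# Descriptive suite (incidence by RBV category, level comparison, timing)
# ---------------------------------------------------------------------------

def _bin_index(rbv: float) -> int:
    for i, (lo, hi) in enumerate(RBV_BINS):
        if lo <= rbv < hi or (i == 0 and rbv >= lo):
            return i
    return len(RBV_BINS) - 1


def descriptive_suite(
    rows: pd.DataFrame,
    risk_by_session: Optional[Dict[str, str]] = None,
    first_event_by_session: Optional[Dict[str, Optional[float]]] = None,
    interval_min: int = 30,
    duration_min: Optional[int] = None,
) -> dict:
    """Descriptive associations between RBV and IDH on concurrent rows.

    Returns a dict with:

    - ``rbv_bins``: per-RBV-category event frequency with a two-sided Fisher
      exact test against the >=95% reference category;
    - ``wilcoxon``: rank-sum comparison of concurrent RBV between flagged and
      unflagged vitals entries (normal approximation, tie-corrected);
    - ``cumulative_by_group`` (when risk groups and first event times are
      given): per-30-min Fisher tests of cumulative IDH incidence between
      high- and low-risk sessions.
    """
    rbv = rows["rbv_pct"].to_numpy(dtype=float)
    lab = rows["label"].to_numpy(dtype=int)
    bins = np.array([_bin_index(v) for v in rbv])
    ref_events = int(lab[bins == 0].sum())
    ref_n = int((bins == 0).sum())
    recs = []
    for i, name in enumerate(RBV_BIN_LABELS):
        n = int((bins == i).sum())
        ev = int(lab[bins == i].sum())
        if n == 0:
            recs.append({"bin": name, "n": 0, "events": 0, "freq": np.nan, "fisher_p": np.nan})
            continue
        if i == 0 or ref_n == 0:
            p = np.nan
        else:
            p = float(fisher_exact([[ev, n - ev], [ref_events, ref_n - ref_events]])[1])
        recs.append({"bin": name, "n": n, "events": ev, "freq": ev / n, "fisher_p": p})
    out = {"rbv_bins": pd.DataFrame(recs)}

    flagged = rbv[lab == 1]
    unflagged = rbv[lab == 0]
    if flagged.size and unflagged.size:
        if np.array_equal(np.sort(flagged), np.sort(unflagged)):
            p = 1.0  # identical samples: no evidence of a shift
        else:
            p = float(
                mannwhitneyu(flagged, unflagged, alternative="two-sided", method="asymptotic")[1]
            )
        out["wilcoxon"] = {
            "median_flagged": float(np.median(flagged)),
            "median_unflagged": float(np.median(unflagged)),
            "p": p,
        }
    else:
        out["wilcoxon"] = None

    if risk_by_session is not None and first_event_by_session is not None:
        if duration_min is None:
            duration_min = int(rows["t_min"].max())
        sess = list(first_event_by_session)
        grp = np.array([risk_by_session[s] for s in sess])
        first = np.array(
            [np.inf if first_event_by_session[s] is None else first_event_by_session[s]
             for s in sess]
        )
        recs = []
        for t in range(interval_min, duration_min + 1, interval_min):
            cum = first <= t
            tab = [
                [int(np.sum(cum & (grp == "high"))), int(np.sum(~cum & (grp == "high")))],
                [int(np.sum(cum & (grp == "low"))), int(np.sum(~cum & (grp == "low")))],
            ]
            recs.append(
                {
                    "t_min": t,
                    "cum_inc_high": tab[0][0] / max(sum(tab[0]), 1),
                    "cum_inc_low": tab[1][0] / max(sum(tab[1]), 1),
                    "fisher_p": float(fisher_exact(tab)[1]),
                }
            )
        out["cumulative_by_group"] = pd.DataFrame(recs)
    return out
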