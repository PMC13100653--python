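"""Mixed-effects logistic regression with a per-patient random intercept.

The model is

    y_ij | b_i ~ Bernoulli(expit(x_ij' beta + b_i)),    b_i ~ N(0, sigma_b^2),

fitted by maximum likelihood: each patient's likelihood contribution
integrates the random intercept by adaptive Gauss–Hermite quadrature
(centered and scaled at the per-patient posterior mode; ``quad_points=1``
reduces to the Laplace approximation, ``sigma_b -> 0`` to plain logistic
regression).  Standard errors come from the inverse observed information.

The interface follows the statsmodels Model/Results convention:

>>> model = MixedLogit.from_formula("label ~ delta_rbv", rows, groups="patient_id")
>>> res = model.fit()
>>> res.summary()
>>> res.odds_ratios()
>>> res.predict(new_rows, use_random_effects=False)

Predictions for patients not seen during fitting always use the fixed
effects only — a patient-specific intercept cannot be estimated for a new
patient, which is exactly why patient-wise validation is harder than
session-wise validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-6  # below this the integral is treated as degenerate at b=0


class ConvergenceError(RuntimeError):
    """Optimizer failed; the message carries the trace.  Complete separation
    typically shows up here — refit with a small ``ridge``."""


def parse_formula(formula: str) -> tuple[str, List[str]]:
    """Parse ``"label ~ a + b + c"`` into (outcome, [features]).

    Deliberately minimal: plain column names joined by ``+`` (an intercept is
    always included; ``1`` terms are ignored)."""
    lhs, _, rhs = formula.partition("~")
    if not rhs:
        raise ValueError(f"formula {formula!r} must contain '~'")
    outcome = lhs.strip()
    feats = [t.strip() for t in rhs.split("+")]
    feats = [f for f in feats if f and f != "1"]
    if not outcome:
        raise ValueError("formula has no outcome")
    return outcome, feats


class MixedLogit:
    """Logistic regression with one Gaussian random intercept per group."""

    def __init__(
        self,
        endog: Sequence[int],
        exog: np.ndarray,
        groups: Sequence,
        exog_names: Optional[List[str]] = None,
        ridge: float = 0.0,
    ):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome is constant; nothing to fit")
        if not np.all(np.isfinite(X)):
            raise ValueError("exog contains non-finite values")
        groups = np.asarray(groups)
        ug, gidx = np.unique(groups, return_inverse=True)
        if ug.size < 2:
            raise ValueError("need at least 2 groups (patients)")
        self.endog = y
        self.exog = X
        self.groups = groups
        self.group_labels = ug
        self.exog_names = list(exog_names) if exog_names else [
            f"x{j}" for j in range(X.shape[1])
        ]
        if len(self.exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self.ridge = float(ridge)
        self._Xg = [X[gidx == g] for g in range(ug.size)]
        self._yg = [y[gidx == g] for g in range(ug.size)]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        groups: str = "patient_id",
        ridge: float = 0.0,
    ) -> "MixedLogit":
        outcome, feats = parse_formula(formula)
        missing = [c for c in [outcome, groups, *feats] if c not in data.columns]
        if missing:
            raise KeyError(f"columns missing from data: {missing}")
        sub = data[[outcome, groups, *feats]].dropna()
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[f].to_numpy(dtype=float) for f in feats]
        )
        model = cls(
            endog=sub[outcome].to_numpy(dtype=float),
            exog=X,
            groups=sub[groups].to_numpy(),
            exog_names=["Intercept", *feats],
            ridge=ridge,
        )
        model.formula = formula
        return model

    # -- likelihood ---------------------------------------------------------

    def _group_mode(self, eta0: np.ndarray, y: np.ndarray, sigma: float):
        """Posterior mode of b_i and the negative curvature there.

        Damped Newton with backtracking: the log-posterior is concave in b,
        but an undamped step can overshoot badly where the logistic curvature
        vanishes, so each step is halved until the objective increases.
        """
        inv_v = 1.0 / (sigma * sigma)

        def obj(b):
            eta = eta0 + b
            return float(np.sum(y * eta - np.logaddexp(0.0, eta))) - 0.5 * b * b * inv_v

        b = 0.0
        f = obj(b)
        for _ in range(100):
            mu = expit(eta0 + b)
            g = float(np.sum(y - mu)) - b * inv_v
            h = float(np.sum(mu * (1.0 - mu))) + inv_v
            step = g / h
            if abs(step) < 1e-11:
                break
            t = 1.0
            bn, fn = b + step, obj(b + step)
            while fn < f and t > 1e-8:
                t *= 0.5
                bn = b + t * step
                fn = obj(bn)
            if fn < f:
                break  # no ascent direction left numerically
            moved = abs(bn - b)
            b, f = bn, fn
            if moved < 1e-11:
                break
        mu = expit(eta0 + b)
        h = float(np.sum(mu * (1.0 - mu))) + inv_v
        return b, h

    def loglike(self, params: np.ndarray, quad_points: int = 21) -> float:
        beta = params[:-1]
        sigma = params[-1]
        ll = 0.0
        if sigma < _SIGMA_FLOOR:
            for X, y in zip(self._Xg, self._yg):
                eta = X @ beta
                ll += float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        else:
            z, w = hermgauss(quad_points)
            logw = np.log(w)
            for X, y in zip(self._Xg, self._yg):
                eta0 = X @ beta
                bhat, h = self._group_mode(eta0, y, sigma)
                s = np.sqrt(2.0 / h)
                b_nodes = bhat + s * z
                eta = eta0[:, None] + b_nodes[None, :]
                f = np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
                f += -0.5 * (b_nodes / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
                m = f + z * z + logw
                mmax = m.max()
                ll += float(np.log(s) + mmax + np.log(np.sum(np.exp(m - mmax))))
        if self.ridge:
            ll -= 0.5 * self.ridge * float(np.sum(beta[1:] ** 2))
        return ll

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
            beta0 = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(beta0)):
                raise ValueError
        except Exception:
            beta0 = np.zeros(self.exog.shape[1])
        return np.concatenate([beta0, [1.0]])

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        quad_points: int = 21,
        start_params: Optional[np.ndarray] = None,
        fix_sigma: Optional[float] = None,
        maxiter: int = 500,
    ) -> "MixedLogitResults":
        start = self._start_params() if start_params is None else np.asarray(start_params, float)
        if fix_sigma is not None:
            sig = float(fix_sigma)

            def nll_b(beta):
                return -self.loglike(np.concatenate([beta, [sig]]), quad_points)

            opt = minimize(nll_b, start[:-1], method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8})
            params = np.concatenate([opt.x, [sig]])
            free = np.arange(self.exog.shape[1])
        else:
            def nll(th):
                return -self.loglike(th, quad_points)

            bounds = [(None, None)] * self.exog.shape[1] + [(0.0, 20.0)]
            opt = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8})
            params = opt.x
            free = np.arange(params.size)
        if not opt.success and "ABNORMAL" not in str(opt.message):
            raise ConvergenceError(
                f"mixed logistic fit failed: {opt.message} (nit={opt.nit}); "
                "complete separation? refit with ridge > 0"
            )
        llf = -float(opt.fun)
        cov = self._cov_params(params, free, quad_points)
        bse_full = np.full(params.size, np.nan)
        bse_full[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        ranef = self._posterior_modes(params)
        grad_norm = float(np.max(np.abs(opt.jac))) if opt.jac is not None else np.nan
        return MixedLogitResults(
            model=self,
            params_all=params,
            bse_all=bse_full,
            cov=cov,
            free_idx=free,
            llf=llf,
            converged=bool(opt.success or "ABNORMAL" in str(opt.message)),
            nit=int(opt.nit),
            grad_norm=grad_norm,
            quad_points=quad_points,
            ranef=ranef,
        )

    def _cov_params(self, params, free, quad_points):
        from statsmodels.tools.numdiff import approx_hess

        def nll_free(th_free):
            th = params.copy()
            th[free] = th_free
            return -self.loglike(th, quad_points)

        H = approx_hess(params[free], nll_free)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def _posterior_modes(self, params) -> pd.Series:
        beta, sigma = params[:-1], params[-1]
        modes = []
        for X, y in zip(self._Xg, self._yg):
            if sigma < _SIGMA_FLOOR:
                modes.append(0.0)
            else:
                b, _ = self._group_mode(X @ beta, y, sigma)
                modes.append(b)
        return pd.Series(modes, index=self.group_labels, name="b_hat")


@dataclass
class MixedLogitResults:
    """Estimates, uncertainties and diagnostics from :meth:`MixedLogit.fit`."""

    model: MixedLogit
    params_all: np.ndarray  # [beta..., sigma_b]
    bse_all: np.ndarray
    cov: np.ndarray
    free_idx: np.ndarray
    llf: float
    converged: bool
    nit: int
    grad_norm: float
    quad_points: int
    ranef: pd.Series

    # -- accessors ----------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_all[:-1], index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.bse_all[:-1], index=self.model.exog_names)

    @property
    def sigma_b(self) -> float:
        return float(self.params_all[-1])

    @property
    def sigma_b_se(self) -> float:
        return float(self.bse_all[-1])

    @property
    def nobs(self) -> int:
        return int(self.model.endog.size)

    @property
    def n_groups(self) -> int:
        return int(self.model.group_labels.size)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.model.exog_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald odds ratios, exp(beta ± z*SE), and p-values (no intercept)."""
        ci = self.conf_int(alpha)
        out = pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(ci["lower"]),
                "ci_high": np.exp(ci["upper"]),
                "p": self.pvalues,
            }
        )
        return out.drop(index="Intercept", errors="ignore")

    # -- prediction ---------------------------------------------------------

    def _design(self, data: Optional[pd.DataFrame]) -> tuple[np.ndarray, np.ndarray]:
        if data is None:
            return self.model.exog, self.model.groups
        feats = [n for n in self.model.exog_names if n != "Intercept"]
        missing = [f for f in feats if f not in data.columns]
        if missing:
            raise KeyError(f"prediction data lacks features {missing}")
        X = np.column_stack(
            [np.ones(len(data))] + [data[f].to_numpy(dtype=float) for f in feats]
        )
        groups = (
            data["patient_id"].to_numpy()
            if "patient_id" in data.columns
            else np.array([None] * len(data))
        )
        return X, groups

    def predict(
        self, data: Optional[pd.DataFrame] = None, use_random_effects: bool = False
    ) -> np.ndarray:
        """Per-row event probability.

        With ``use_random_effects`` the posterior-mode intercept of each
        *training* patient is added; patients unseen at fit time always get
        the fixed effects only.
        """
        X, groups = self._design(data)
        eta = X @ self.params_all[:-1]
        if use_random_effects:
            bmap = self.ranef.to_dict()
            eta = eta + np.array([bmap.get(g, 0.0) for g in groups])
        return expit(eta)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Mixed-effects logistic regression (patient random intercept)",
            "=" * 64,
            f"No. observations: {self.nobs:<8d} No. patients: {self.n_groups}",
            f"Log-likelihood:   {self.llf:<12.3f} Quadrature nodes: {self.quad_points}",
            f"Converged: {self.converged}   iterations: {self.nit}   "
            f"max|grad|: {self.grad_norm:.2e}",
            "-" * 64,
            f"{'term':<18}{'coef':>10}{'SE':>9}{'OR':>9}{'z':>8}{'P>|z|':>9}",
        ]
        for name in self.model.exog_names:
            b, se = self.params[name], self.bse[name]
            z = b / se if se > 0 else np.nan
            p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(
                f"{name:<18}{b:>10.4f}{se:>9.4f}{np.exp(b):>9.3f}{z:>8.2f}{p:>9.4f}"
            )
        lines.append("-" * 64)
        lines.append(
            f"Random intercept SD (sigma_b): {self.sigma_b:.4f}"
            + (f"  (SE {self.sigma_b_se:.4f})" if np.isfinite(self.sigma_b_se) else "")
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "odds_ratios": self.odds_ratios().to_dict(orient="index"),
            "sigma_b": self.sigma_b,
            "sigma_b_se": self.sigma_b_se,
            "llf": self.llf,
            "converged": self.converged,
            "nobs": self.nobs,
            "n_groups": self.n_groups,
        }


# ---------------------------------------------------------------------------
# Convenience fits for the standard analyses
# ---------------------------------------------------------------------------

def fit_mixed_logistic(
    rows: pd.DataFrame,
    formula: str,
    groups: str = "patient_id",
    quad_points: int = 21,
    **fit_kw,
) -> MixedLogitResults:
    """One-call fit of ``formula`` on a prediction-row table."""
    return MixedLogit.from_formula(formula, rows, groups=groups).fit(
        quad_points=quad_points, **fit_kw
    )


def fit_association_suite(
    rows: pd.DataFrame,
    risk_by_session: Optional[Dict[str, str]] = None,
    quad_points: int = 21,
) -> Dict[str, MixedLogitResults]:
    """The three concurrent association models.

    ``label ~ delta_rbv`` (continuous), ``label ~ high_risk`` (session-level
    cluster risk group, if provided) and ``label ~ below_threshold`` (if the
    rows carry the indicator), each with a patient random intercept.
    """
    out: Dict[str, MixedLogitResults] = {}
    out["delta_rbv"] = fit_mixed_logistic(rows, "label ~ delta_rbv", quad_points=quad_points)
    if risk_by_session is not None:
        rows = rows.copy()
        rows["high_risk"] = (
            rows["session_id"].map(risk_by_session).eq("high").astype(float)
        )
        out["risk_group"] = fit_mixed_logistic(
            rows, "label ~ high_risk", quad_points=quad_points
        )
    if "below_threshold" in rows.columns and rows["below_threshold"].notna().any():
        out["below_threshold"] = fit_mixed_logistic(
            rows, "label ~ below_threshold", quad_points=quad_points
        )
    return out


def association_table(fits: Dict[str, MixedLogitResults]) -> pd.DataFrame:
    """Tidy OR table (one row per model's exposure term)."""
    recs = []
    for name, res in fits.items():
        term = [n for n in res.model.exog_names if n != "Intercept"][0]
        ors = res.odds_ratios().loc[term]
        recs.append(
            {
                "model": name,
                "term": term,
                "OR": ors["OR"],
                "ci_low": ors["ci_low"],
                "ci_high": ors["ci_high"],
                "p": ors["p"],
                "sigma_b": res.sigma_b,
            }
        )
    return pd.DataFrame(recs)


def fit_predictive_model(
    rows: pd.DataFrame,
    covariates: Sequence[str] = ("delta_rbv",),
    quad_points: int = 21,
    **fit_kw,
) -> MixedLogitResults:
    """Horizon-mode predictive GLMM: ``label ~ cov1 + cov2 + ...``."""
    formula = "label ~ " + " + ".join(covariates)
    return fit_mixed_logistic(rows, formula, quad_points=quad_points, **fit_kw)
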