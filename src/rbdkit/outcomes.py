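"""Repeated-measures mixed model for treatment-moderation analysis.

The model follows the standard moderator design for a two-arm trial with
a baseline behavioral classification: HAMD-17 at the post-baseline weeks
(1, 2, 3, 4, 6, 8) is regressed on the week-0 score (covariate),
treatment arm, engagement label, the natural log of week, and all
treatment x engagement x log-week interactions.  Each subject gets a
random intercept, and the within-subject residuals follow a *spatial
power* covariance: corr(e_ij, e_ik) = rho^|t_ij - t_ik| over the
real-valued week axis, the continuous-time generalization of lag-1
autoregression that handles the unequal 4 -> 6 -> 8 week spacing exactly.

Estimation is restricted maximum likelihood (REML) with the residual
variance profiled out, leaving a two-parameter optimization over
gamma = var(intercept)/var(residual) and rho, run from multiple starts.
The moderation test is a Wald test of the three-way interaction
coefficient (large-sample z by default; a residual-df t/F variant is
available via ``df_method="residual"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .types import VisitRecord

FIXED_EFFECTS = ("intercept", "baseline", "treat", "disengaged", "logweek",
                 "treat:disengaged", "treat:logweek", "disengaged:logweek",
                 "treat:disengaged:logweek")
THREE_WAY = "treat:disengaged:logweek"


class ConvergenceError(RuntimeError):
    """REML optimization failed from every start; carries the trace."""


class RankDeficiencyError(ValueError):
    """A treatment x engagement design cell is empty."""


@dataclass(frozen=True)
class ModelSpec:
    """Options for the moderation fit."""

    df_method: str = "wald"          # "wald" (large-sample z) or "residual"
    rho_starts: tuple = (0.0, 0.3, 0.6)
    tol: float = 1e-8
    max_week: float = 8.0


@dataclass
class ModerationResult:
    params: pd.Series                # fixed-effect estimates
    bse: pd.Series                   # standard errors
    sigma_resid: float               # residual SD
    sigma_intercept: float           # random-intercept SD
    rho: float                       # spatial-power correlation per week
    loglike_reml: float
    interaction_stat: float          # Wald chi-square (1 df) for the 3-way term
    interaction_df: tuple            # (num df, denom df or inf)
    interaction_p: float
    n_obs: int
    n_subjects: int
    mean_baseline: float
    converged: bool = True
    optimizer_trace: list = field(default_factory=list)
    spec: ModelSpec = ModelSpec()


def visits_to_frame(visits: Sequence[VisitRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"subject_id": v.subject_id, "week": v.week,
                          "hamd17": v.hamd17, "treatment": v.treatment}
                         for v in visits])


def build_design(visits: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Merge visits with engagement labels into the analysis frame.

    ``labels`` maps subject_id -> "engaged"/"disengaged".  The week-0
    score becomes the per-subject baseline covariate; subjects without a
    week-0 visit or any post-baseline visit are dropped.
    """
    df = visits.copy()
    df["disengaged"] = df["subject_id"].map(
        lambda s: {"engaged": 0, "disengaged": 1}.get(labels.get(s)))
    df = df.dropna(subset=["disengaged"])
    base = (df[df["week"] == 0].set_index("subject_id")["hamd17"]
            .rename("baseline"))
    df = df[df["week"] > 0].join(base, on="subject_id").dropna(subset=["baseline"])
    df["treat"] = (df["treatment"] == "sertraline").astype(int)
    df["logweek"] = np.log(df["week"].astype(float))
    df["disengaged"] = df["disengaged"].astype(int)
    return df.reset_index(drop=True)


def _design_matrix(df: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([
        np.ones(len(df)),
        df["baseline"].to_numpy(float),
        df["treat"].to_numpy(float),
        df["disengaged"].to_numpy(float),
        df["logweek"].to_numpy(float),
        (df["treat"] * df["disengaged"]).to_numpy(float),
        (df["treat"] * df["logweek"]).to_numpy(float),
        (df["disengaged"] * df["logweek"]).to_numpy(float),
        (df["treat"] * df["disengaged"] * df["logweek"]).to_numpy(float),
    ])
    return X


class SpatialPowerMixedModel:
    """Random-intercept linear mixed model with spatial-power residuals.

    Marginal covariance per subject: V_i = sigma_b^2 J + sigma^2 R_i(rho),
    R_i(rho)[j,k] = rho^|t_j - t_k|.  REML with sigma^2 profiled; subjects
    sharing an identical visit-time pattern are batched for speed.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 subjects: np.ndarray, times: np.ndarray):
        order = np.lexsort((times, subjects))
        y, X, subjects, times = y[order], X[order], subjects[order], times[order]
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise RankDeficiencyError(
                "fixed-effect design is rank deficient (an empty "
                "treatment x engagement cell or constant column)")
        # batch subjects by identical visit-time pattern
        self._batches = []   # (gap_matrix, X_stack, X_flat, y_stack)
        by_pattern: dict = {}
        for sid in pd.unique(subjects):
            m = subjects == sid
            key = tuple(np.round(times[m], 6))
            by_pattern.setdefault(key, []).append((X[m], y[m]))
        for key, items in by_pattern.items():
            t = np.asarray(key, float)
            Xs = np.stack([x for x, _ in items])       # (m, k, p)
            ys = np.stack([v for _, v in items])       # (m, k)
            gaps = np.abs(t[:, None] - t[None, :])
            self._batches.append((gaps, Xs, Xs.reshape(-1, self.p), ys))
        self.n_subjects = int(pd.unique(subjects).size)

    def _neg2_reml(self, gamma: float, rho: float,
                   with_constant: bool = True):
        XtWX = np.zeros((self.p, self.p))
        XtWy = np.zeros(self.p)
        ytWy = 0.0
        logdet = 0.0
        for gaps, Xs, Xflat, ys in self._batches:
            k = gaps.shape[0]
            R = rho ** gaps if rho != 0.0 else np.eye(k)
            W = gamma * np.ones((k, k)) + R
            try:
                c, low = linalg.cho_factor(W)
            except linalg.LinAlgError:
                return None
            Winv = linalg.cho_solve((c, low), np.eye(k))
            logdet += Xs.shape[0] * 2.0 * np.sum(np.log(np.diag(c)))
            tmp = np.matmul(Winv, Xs)                  # (m, k, p)
            XtWX += Xflat.T @ tmp.reshape(-1, self.p)
            wy = ys @ Winv                             # (m, k), Winv symmetric
            XtWy += Xflat.T @ wy.ravel()
            ytWy += float((ys * wy).sum())
        try:
            cf = linalg.cho_factor(XtWX)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cf, XtWy)
        rss = ytWy - float(XtWy @ beta)
        dof = self.n - self.p
        if rss <= 0:
            return None
        sigma2 = rss / dof
        logdet_xtwx = 2.0 * np.sum(np.log(np.diag(cf[0])))
        crit = dof * math.log(sigma2) + logdet + logdet_xtwx + dof
        if with_constant:
            crit += dof * math.log(2.0 * math.pi)
        return crit, beta, sigma2, XtWX

    def fit(self, rho_starts=(0.0, 0.3, 0.6), tol: float = 1e-8):
        trace = []

        def objective(theta):
            gamma = math.exp(theta[0])
            rho = math.tanh(theta[1])
            out = self._neg2_reml(gamma, rho)
            val = 1e12 if out is None else out[0]
            trace.append((gamma, rho, val))
            return val

        # evaluate every start, polish from the best with Nelder-Mead
        starts = [np.array([0.0, math.atanh(min(max(r, -0.98), 0.98))])
                  for r in rho_starts]
        start_vals = [objective(t) for t in starts]
        order = np.argsort(start_vals)
        best = None
        for idx in order:
            res = optimize.minimize(objective, starts[idx], method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": tol,
                                             "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
            if res.success and np.isfinite(res.fun) and res.fun < 1e12:
                break
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise ConvergenceError(
                f"REML optimization failed; trace tail: {trace[-10:]}")
        gamma = math.exp(best.x[0])
        rho = math.tanh(best.x[1])
        crit, beta, sigma2, XtWX = self._neg2_reml(gamma, rho)
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        return {
            "beta": beta, "cov_beta": cov_beta, "sigma2": sigma2,
            "gamma": gamma, "rho": rho, "neg2_reml": crit,
            "converged": bool(best.success), "trace": trace,
        }


def fit_moderation_model(visits, labels: dict,
                         spec: ModelSpec = ModelSpec()) -> ModerationResult:
    """Fit the moderation mixed model and test the 3-way interaction.

    Parameters
    ----------
    visits : sequence of VisitRecord or DataFrame with the visit schema
    labels : dict subject_id -> "engaged"/"disengaged"
    """
    df = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    frame = build_design(df, labels)
    if frame.empty:
        raise ValueError("no analyzable post-baseline visits")
    cells = frame.groupby(["treat", "disengaged"]).size()
    for tr in (0, 1):
        for dis in (0, 1):
            if (tr, dis) not in cells.index:
                raise RankDeficiencyError(
                    f"empty design cell: treat={tr}, disengaged={dis}")
    X = _design_matrix(frame)
    y = frame["hamd17"].to_numpy(float)
    model = SpatialPowerMixedModel(y, X, frame["subject_id"].to_numpy(),
                                   frame["week"].to_numpy(float))
    fit = model.fit(rho_starts=spec.rho_starts, tol=spec.tol)
    beta = pd.Series(fit["beta"], index=FIXED_EFFECTS)
    bse = pd.Series(np.sqrt(np.diag(fit["cov_beta"])), index=FIXED_EFFECTS)
    z = beta[THREE_WAY] / bse[THREE_WAY]
    if spec.df_method == "residual":
        ddf = model.n - model.p
        p = 2.0 * stats.t.sf(abs(z), ddf)
        dfs = (1, ddf)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        dfs = (1, math.inf)
    return ModerationResult(
        params=beta, bse=bse,
        sigma_resid=math.sqrt(fit["sigma2"]),
        sigma_intercept=math.sqrt(fit["gamma"] * fit["sigma2"]),
        rho=fit["rho"],
        loglike_reml=-0.5 * fit["neg2_reml"],
        interaction_stat=float(z * z), interaction_df=dfs,
        interaction_p=float(p), n_obs=model.n, n_subjects=model.n_subjects,
        mean_baseline=float(frame["baseline"].mean()),
        converged=fit["converged"], optimizer_trace=fit["trace"], spec=spec)


def fitted_trajectories(result: ModerationResult,
                        weeks: Sequence[float]) -> pd.DataFrame:
    """Predicted HAMD-17 per treatment x engagement cell at the mean baseline."""
    rows = []
    b = result.params
    for w in weeks:
        if w <= 0:
            raise ValueError("fitted trajectories are defined for weeks > 0")
        if w > result.spec.max_week:
            warnings.warn(f"extrapolating beyond week {result.spec.max_week}",
                          stacklevel=2)
        lw = math.log(w)
        for treat in (0, 1):
            for dis in (0, 1):
                pred = (b["intercept"] + b["baseline"] * result.mean_baseline
                        + b["treat"] * treat + b["disengaged"] * dis
                        + b["logweek"] * lw
                        + b["treat:disengaged"] * treat * dis
                        + b["treat:logweek"] * treat * lw
                        + b["disengaged:logweek"] * dis * lw
                        + b["treat:disengaged:logweek"] * treat * dis * lw)
                rows.append({
                    "week": float(w),
                    "treatment": "sertraline" if treat else "placebo",
                    "label": "disengaged" if dis else "engaged",
                    "hamd17_pred": float(pred),
                })
    return pd.DataFrame(rows)


def plot_trajectories(result: ModerationResult,
                      weeks=(1, 2, 3, 4, 6, 8), path: Optional[str] = None):
    """Minimal two-panel trajectory plot (engaged | disengaged)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = fitted_trajectories(result, weeks)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    for ax, label in zip(axes, ("disengaged", "engaged")):
        sub = curves[curves["label"] == label]
        for treatment, grp in sub.groupby("treatment"):
            ax.plot(grp["week"], grp["hamd17_pred"], marker="o", label=treatment)
        ax.set_title(label)
        ax.set_xlabel("week")
    axes[0].set_ylabel("HAMD-17 (model)")
    axes[0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
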