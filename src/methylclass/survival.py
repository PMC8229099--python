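"""Within-subtype outcome analysis.

Ranks CpGs that separate relapsing from non-relapsing patients, splits
patients into high/low methylation groups by hierarchical clustering of
the top-ranked CpGs, and compares relapse-free and overall survival
between the groups with the Kaplan-Meier estimator, the log-rank test
and a Cox proportional-hazards fit (Newton-Raphson partial likelihood
with Breslow tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import mannwhitney_u
from .heterogeneity import hier_cluster
from .types import BetaMatrix, SampleSheet

__all__ = [
    "SurvivalGrouping",
    "CoxFit",
    "rank_outcome_cpgs",
    "assign_methylation_groups",
    "km_curve",
    "logrank_test",
    "cox_ph_fit",
    "plot_km",
    "run_survival_stage",
]

ENDPOINTS = ("rfs", "os")


def rank_outcome_cpgs(
    beta_fs_subtype: BetaMatrix,
    relapse_flag,
    alpha: float = 0.05,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank CpGs separating relapse from no-relapse samples.

    Per CpG, a Mann-Whitney test between the two outcome groups; CpGs
    with raw p < ``alpha`` are kept and the best ``top_k`` are returned
    ordered by ascending p (ties by larger absolute mean difference, then
    CpG ID).  Returns a DataFrame with cpg_id, U, p and delta_beta.
    """
    flag = np.asarray(pd.Series(relapse_flag).to_numpy()).astype(bool)
    if len(flag) != beta_fs_subtype.n_samples:
        raise ValueError("relapse_flag length must match samples")
    if flag.all() or not flag.any():
        raise ValueError("both relapse classes must be non-empty")
    values = beta_fs_subtype.values
    rows = []
    for i, cpg in enumerate(beta_fs_subtype.cpg_ids):
        xv = values[i, flag]
        yv = values[i, ~flag]
        xv = xv[~np.isnan(xv)]
        yv = yv[~np.isnan(yv)]
        if xv.size == 0 or yv.size == 0:
            continue
        u, p = mannwhitney_u(xv, yv)
        if p < alpha:
            rows.append({"cpg_id": cpg, "U": u, "p": p,
                         "delta_beta": float(xv.mean() - yv.mean())})
    df = pd.DataFrame(rows, columns=["cpg_id", "U", "p", "delta_beta"])
    if df.empty:
        return df
    df["abs_delta"] = df["delta_beta"].abs()
    df = df.sort_values(["p", "abs_delta", "cpg_id"],
                        ascending=[True, False, True], kind="stable")
    return df.drop(columns="abs_delta").head(top_k).reset_index(drop=True)


def assign_methylation_groups(beta_topk: BetaMatrix, k: int = 2,
                              ) -> dict[str, str]:
    """Cluster samples on the selected CpGs into high/low groups.

    Hierarchical clustering (same engine as the heterogeneity stage) cut
    at ``k``; the cluster with the larger mean beta is labeled ``high``
    (tie: the cluster containing the lexically smallest sample ID).
    """
    if beta_topk.n_samples < 2:
        raise ValueError("need at least 2 samples")
    assignment = hier_cluster(beta_topk, k=k)
    df = beta_topk.data
    means = {}
    for label in assignment.labels:
        members = assignment.members(label)
        means[label] = float(np.nanmean(df[members].to_numpy()))
    # higher mean = "high"; ties favor the cluster with the smallest ID
    ranked = sorted(assignment.labels,
                    key=lambda c: (-means[c], min(assignment.members(c))))
    names = {ranked[0]: "high", ranked[1]: "low"} if k == 2 else {
        c: f"group{i}" for i, c in enumerate(ranked)}
    return {sid: names[c] for sid, c in assignment.assignment.items()}


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns a step function DataFrame (time, survival, n_at_risk, n_events)
    starting at t = 0 with survival 1; censored subjects leave the risk
    set after their time.
    """
    t = np.asarray(times, float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty input")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be binary")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order].astype(int)
    rows = [{"time": 0.0, "survival": 1.0, "n_at_risk": int(t.size),
             "n_events": 0}]
    surv = 1.0
    n_at_risk = t.size
    for ti in np.unique(t):
        at_this = t == ti
        d = int(e[at_this].sum())
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            rows.append({"time": float(ti), "survival": surv,
                         "n_at_risk": int(n_at_risk), "n_events": d})
        n_at_risk -= int(at_this.sum())
    return pd.DataFrame(rows)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    Chi-square statistic ``(sum(O1 - E1))^2 / sum(V)`` over distinct event
    times with hypergeometric expectations and variances; p from the
    chi-square distribution with 1 df.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    g = np.asarray(pd.Series(groups).to_numpy())
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank requires exactly 2 non-empty groups")
    if e.sum() == 0:
        warnings.warn("no events; log-rank p = 1", stacklevel=2)
        return 0.0, 1.0
    in1 = g == labels[0]
    obs_minus_exp = 0.0
    var_sum = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var_sum == 0:
        warnings.warn("zero log-rank variance; p = 1", stacklevel=2)
        return 0.0, 1.0
    chi2 = obs_minus_exp ** 2 / var_sum
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CoxFit:
    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation: bool = False
    n_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.coefficients,
            "hazard_ratio": self.hazard_ratios,
            "se": self.standard_errors,
            "p": self.p_values,
        })


def _cox_loglik(beta, t, e, x):
    """Breslow partial log-likelihood with gradient and information."""
    eta = x @ beta
    # cap to avoid overflow during separation
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-t, kind="stable")  # descending time
    t_o, e_o, x_o, w_o = t[order], e[order], x[order], w[order]
    n, p = x.shape
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        ti = t_o[i]
        j = i
        while j < n and t_o[j] == ti:
            s0 += w_o[j]
            s1 += w_o[j] * x_o[j]
            s2 += w_o[j] * np.outer(x_o[j], x_o[j])
            j += 1
        deaths = [m for m in range(i, j) if e_o[m] == 1]
        d = len(deaths)
        if d > 0:
            xbar = s1 / s0
            for m in deaths:
                ll += (x_o[m] @ beta)
            ll -= d * np.log(s0)
            grad += x_o[deaths].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, info


def cox_ph_fit(
    times,
    events,
    covariates,
    covariate_names=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson (Breslow ties).

    Wald standard errors come from the inverse observed information.
    Monotone likelihood (separation) is detected by runaway coefficients,
    which are capped with a warning rather than silently returned.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    x = np.atleast_2d(np.asarray(covariates, float))
    if x.shape[0] != t.size:
        x = x.T
    if x.shape[0] != t.size:
        raise ValueError("covariate rows must match number of subjects")
    if e.sum() == 0:
        raise ValueError("no events; Cox model cannot be fit")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant covariate column")
    names = (list(covariate_names) if covariate_names is not None
             else [f"x{i}" for i in range(x.shape[1])])

    # standardize for numerical stability; back-transform at the end
    scale = x.std(axis=0, ddof=0)
    xs = (x - x.mean(axis=0)) / scale

    beta = np.zeros(x.shape[1])
    converged = False
    separation = False
    cap = 10.0  # on the standardized scale; beyond this lies separation
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(beta, t, e, xs)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step halving if the likelihood does not improve
        new_beta = beta + step
        for _ in range(30):
            ll_new, _, _ = _cox_loglik(new_beta, t, e, xs)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
        beta = new_beta
        if np.abs(beta).max() > cap:
            separation = True
            beta = np.clip(beta, -cap, cap)
            break
        if abs(ll_new - ll_old) < tol:
            converged = True
            break
        ll_old = ll_new
    if separation:
        warnings.warn("monotone likelihood (separation); coefficients capped",
                      stacklevel=2)
    if not converged and not separation:
        warnings.warn("Cox fit did not converge", stacklevel=2)

    _, _, info = _cox_loglik(beta, t, e, xs)
    try:
        cov = np.linalg.inv(info)
        se_s = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_s = np.full(beta.size, np.nan)
    coef = beta / scale
    se = se_s / scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(names, coef, np.exp(coef), se, p,
                  converged=converged, separation=separation,
                  n_events=int(e.sum()))


def plot_km(curves: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Optional step plot of per-group KM curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"high": "tab:red", "low": "tab:blue"}
    for label, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post",
                label=label, color=colors.get(label))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class SurvivalGrouping:
    subtype: str
    selected: pd.DataFrame  # cpg_id, U, p, delta_beta
    groups: dict[str, str]  # sample_id -> high/low
    km: dict[str, dict[str, pd.DataFrame]]  # endpoint -> group -> curve
    logrank: dict[str, tuple[float, float]]  # endpoint -> (chi2, p)
    event_free: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def selected_cpgs(self) -> list[str]:
        return list(self.selected["cpg_id"])


def run_survival_stage(
    beta_fs: BetaMatrix,
    sheet: SampleSheet,
    subtype: str,
    include_predicted: bool = False,
    predicted: dict[str, str] | None = None,
    exclusions=(),
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    top_k: int = 50,
) -> tuple[SurvivalGrouping, dict[str, CoxFit]]:
    """Outcome analysis for one subtype's diagnostic samples.

    Restricts to diagnostic samples reported as ``subtype`` (adding
    classifier-predicted members from ``predicted`` when
    ``include_predicted``; removing ``exclusions``), then chains CpG
    ranking -> group assignment -> KM/log-rank per endpoint -> Cox fit on
    the group indicator plus optional extra covariates.
    """
    df = sheet.data
    diag = df[df["timepoint"] == "diagnosis"]
    members = list(diag.loc[diag["reported_subtype"] == subtype, "sample_id"])
    if include_predicted and predicted:
        undefined = diag.loc[diag["reported_subtype"] == "undefined",
                             "sample_id"]
        members += [s for s in undefined
                    if predicted.get(s) == subtype and s not in members]
    members = [s for s in members if s not in set(exclusions)
               and s in set(beta_fs.sample_ids)]
    if len(members) < 2:
        raise ValueError(f"too few samples for subtype {subtype!r}")

    sub_sheet = sheet.loc_samples(members)
    relapse = pd.to_numeric(sub_sheet.data["rfs_event"]).to_numpy()
    beta_sub = beta_fs.subset_samples(members)

    ranked = rank_outcome_cpgs(beta_sub, relapse, alpha=alpha, top_k=top_k)
    if ranked.empty:
        raise ValueError("no CpGs pass the outcome screen")
    groups = assign_methylation_groups(beta_sub.subset_cpgs(
        ranked["cpg_id"]))

    group_arr = np.array([groups[s] for s in members])
    km: dict[str, dict[str, pd.DataFrame]] = {}
    logrank: dict[str, tuple[float, float]] = {}
    event_free: dict[str, dict[str, float]] = {}
    cox: dict[str, CoxFit] = {}
    for ep in ENDPOINTS:
        t = pd.to_numeric(sub_sheet.data[f"{ep}_time"]).to_numpy()
        e = pd.to_numeric(sub_sheet.data[f"{ep}_event"]).to_numpy()
        km[ep] = {}
        event_free[ep] = {}
        for label in ("high", "low"):
            mask = group_arr == label
            if mask.any():
                km[ep][label] = km_curve(t[mask], e[mask])
                event_free[ep][label] = float(1 - e[mask].mean())
        logrank[ep] = logrank_test(t, e, group_arr)
        cov_cols = ["methylation_high"]
        cov = (group_arr == "high").astype(float)[:, None]
        if covariates is not None:
            extra = covariates.loc[members]
            cov = np.column_stack([cov, extra.to_numpy(float)])
            cov_cols += list(extra.columns)
        try:
            cox[ep] = cox_ph_fit(t, e, cov, covariate_names=cov_cols)
        except ValueError as err:
            warnings.warn(f"Cox fit skipped for {ep}: {err}", stacklevel=2)
    grouping = SurvivalGrouping(subtype, ranked, groups, km, logrank,
                                event_free)
    return grouping, cox
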