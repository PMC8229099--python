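"""Per-subtype one-vs-rest differential methylation.

Mann-Whitney U per CpG (subtype vs all remaining samples), with
Benjamini-Hochberg correction applied within each subtype across CpGs,
and extraction of the CpGs unique to a single subtype's significant set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import BetaMatrix

__all__ = ["DiffResult", "mannwhitney_u", "bh_adjust", "one_vs_rest_dm",
           "unique_cpgs"]


def mannwhitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U of ``x`` vs ``y`` with a two-sided p-value.

    ``mode='auto'`` uses the exact null distribution when the combined
    sample size is at most 12 and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.  ``mode`` may be
    forced to ``'exact'`` or ``'asymptotic'``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        combined = np.concatenate([x, y])
        no_ties = np.unique(combined).size == combined.size
        mode = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode: {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=mode,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class DiffResult:
    """Long-format per-(subtype, CpG) statistics plus per-subtype sets."""

    table: pd.DataFrame  # subtype, cpg_id, U, p, adj_p, delta_beta, significant
    significant: dict[str, set[str]] = field(default_factory=dict)
    unique: dict[str, set[str]] = field(default_factory=dict)
    skipped_subtypes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["unique"] = [cpg in self.unique.get(s, set())
                        for s, cpg in zip(df["subtype"], df["cpg_id"])]
        return df


def one_vs_rest_dm(
    beta_fs: BetaMatrix,
    labels,
    alpha: float = 0.05,
    min_group: int = 3,
) -> DiffResult:
    """One-vs-rest Mann-Whitney per subtype with BH within subtype.

    Subtypes with fewer than ``min_group`` samples are skipped with a
    warning.  ``delta_beta`` is the subtype mean minus the rest mean.
    """
    y = np.asarray(pd.Series(labels).to_numpy()).astype(str)
    if len(y) != beta_fs.n_samples:
        raise ValueError("labels length must match samples")
    subtypes = sorted(set(y))
    if len(subtypes) < 2:
        raise ValueError("need at least 2 classes")

    values = beta_fs.values
    cpgs = beta_fs.cpg_ids
    rows = []
    significant: dict[str, set[str]] = {}
    skipped = []
    for s in subtypes:
        in_group = y == s
        if in_group.sum() < min_group:
            skipped.append(s)
            warnings.warn(
                f"subtype {s!r} has {int(in_group.sum())} samples "
                f"(< {min_group}); skipped", stacklevel=2)
            continue
        pvals, stats_u, deltas = [], [], []
        for i in range(len(cpgs)):
            xv = values[i, in_group]
            yv = values[i, ~in_group]
            xv = xv[~np.isnan(xv)]
            yv = yv[~np.isnan(yv)]
            if xv.size == 0 or yv.size == 0:
                stats_u.append(np.nan)
                pvals.append(1.0)
                deltas.append(np.nan)
                continue
            u, p = mannwhitney_u(xv, yv)
            stats_u.append(u)
            pvals.append(p)
            deltas.append(float(xv.mean() - yv.mean()))
        adj = bh_adjust(pvals)
        sig = {cpgs[i] for i in range(len(cpgs)) if adj[i] < alpha}
        significant[s] = sig
        for i, cpg in enumerate(cpgs):
            rows.append({"subtype": s, "cpg_id": cpg, "U": stats_u[i],
                         "p": pvals[i], "adj_p": adj[i],
                         "delta_beta": deltas[i], "significant": cpg in sig})
    table = pd.DataFrame(
        rows, columns=["subtype", "cpg_id", "U", "p", "adj_p", "delta_beta",
                       "significant"])
    result = DiffResult(table, significant, {}, skipped)
    result.unique = unique_cpgs(result)
    return result


def unique_cpgs(result: DiffResult) -> dict[str, set[str]]:
    """CpGs significant in exactly one subtype: sig(s) minus all others."""
    unique: dict[str, set[str]] = {}
    for s, sig in result.significant.items():
        others: set[str] = set()
        for t, other in result.significant.items():
            if t != s:
                others |= other
        unique[s] = sig - others
    return unique
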