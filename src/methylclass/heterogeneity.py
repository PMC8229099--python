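"""Intra-subtype heterogeneity: hierarchical clustering and association.

Samples of one subtype are split by agglomerative clustering over the
selected CpGs; the resulting clusters are compared against binary
features (mutation flags, sex) with Fisher's exact test and against
continuous features (age) with Welch's t-test.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .types import MUTATION_COLUMNS, BetaMatrix, SampleSheet

__all__ = ["ClusterAssignment", "hier_cluster", "fisher_exact_2x2",
           "two_sample_ttest", "associate_clusters"]


@dataclass
class ClusterAssignment:
    """Sample-to-cluster map; clusters named A, B, ... by ascending mean beta."""

    assignment: dict[str, str]
    linkage_method: str
    metric: str
    k: int

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if len(labels) < self.k:
            raise ValueError("some clusters are empty")

    def members(self, label: str) -> list[str]:
        return sorted(s for s, c in self.assignment.items() if c == label)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def _imputed_sample_matrix(beta: BetaMatrix) -> np.ndarray:
    df = beta.data
    if df.isna().any().any():
        df = df.T.fillna(df.median(axis=1)).T
    return df.to_numpy().T  # samples x CpGs


def hier_cluster(
    beta_sub: BetaMatrix,
    k: int = 2,
    linkage_method: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Agglomerative dendrogram over samples, cut to ``k`` clusters.

    Samples are ordered lexically by ID before linkage so the result is
    independent of input order (ties merge the lower sample ID first).
    Clusters are named A, B, ... by ascending mean beta.
    """
    if beta_sub.n_samples < k:
        raise ValueError(f"need at least k={k} samples")
    order = np.argsort(np.asarray(beta_sub.sample_ids))
    ids = [beta_sub.sample_ids[i] for i in order]
    x = _imputed_sample_matrix(beta_sub)[order]
    z = linkage(x, method=linkage_method, metric=metric)
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        # degenerate dendrogram (e.g. identical samples): deterministic
        # fallback split by lexical sample order
        raw = np.array([i * k // len(ids) + 1 for i in range(len(ids))])
    # name clusters by ascending mean beta
    means = {c: x[raw == c].mean() for c in np.unique(raw)}
    ranked = sorted(means, key=lambda c: (means[c],
                                          min(np.where(raw == c)[0])))
    names = {c: string.ascii_uppercase[i] for i, c in enumerate(ranked)}
    assignment = {sid: names[c] for sid, c in zip(ids, raw)}
    return ClusterAssignment(assignment, linkage_method, metric, k)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables with the same
    margins that are no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def two_sample_ttest(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided).

    Degenerate case (zero variance in both groups, equal means) returns
    p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            warnings.warn("zero variance in both groups with equal means",
                          stacklevel=2)
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


_BINARY_FEATURES = [*MUTATION_COLUMNS, "any_mutation", "sex"]
_CONTINUOUS_FEATURES = ["age"]


def _binary_series(sheet_df: pd.DataFrame, feature: str) -> pd.Series:
    if feature == "any_mutation":
        muts = sheet_df[MUTATION_COLUMNS].apply(pd.to_numeric, errors="coerce")
        # OR over the panel; all-unknown rows stay unknown
        any_mut = (muts == 1).any(axis=1).astype(float)
        any_mut[muts.isna().all(axis=1)] = np.nan
        return any_mut
    if feature == "sex":
        s = sheet_df["sex"].astype(str)
        out = pd.Series(np.nan, index=sheet_df.index)
        out[s.str.upper().isin(["F", "FEMALE"])] = 1.0
        out[s.str.upper().isin(["M", "MALE"])] = 0.0
        return out
    return pd.to_numeric(sheet_df[feature], errors="coerce")


def associate_clusters(assignment: ClusterAssignment, sheet: SampleSheet,
                       ) -> pd.DataFrame:
    """Per-feature two-cluster association tests.

    Binary features (each mutation flag, the derived any-mutation flag,
    sex) use Fisher's exact test on a 2x2 table excluding unknowns;
    continuous features (age) use Welch's t-test.  Features with all
    values unknown are skipped with a warning.
    """
    if assignment.k != 2:
        raise ValueError("association requires exactly 2 clusters")
    label_a, label_b = assignment.labels[:2]
    ids_a = assignment.members(label_a)
    ids_b = assignment.members(label_b)
    df = sheet.data.set_index("sample_id")
    sub_a = df.loc[ids_a].reset_index()
    sub_b = df.loc[ids_b].reset_index()

    rows = []
    for feature in _BINARY_FEATURES:
        va = _binary_series(sub_a, feature).dropna()
        vb = _binary_series(sub_b, feature).dropna()
        if va.empty and vb.empty:
            warnings.warn(f"feature {feature!r} all unknown; skipped",
                          stacklevel=2)
            continue
        table = [[int((va == 1).sum()), int((va == 0).sum())],
                 [int((vb == 1).sum()), int((vb == 0).sum())]]
        p = fisher_exact_2x2(table)
        rows.append({"feature": feature, "n_A": int(va.size),
                     "n_B": int(vb.size),
                     "summary_A": f"{int((va == 1).sum())}/{int(va.size)}",
                     "summary_B": f"{int((vb == 1).sum())}/{int(vb.size)}",
                     "test": "fisher", "p": p})
    for feature in _CONTINUOUS_FEATURES:
        va = pd.to_numeric(sub_a[feature], errors="coerce").dropna()
        vb = pd.to_numeric(sub_b[feature], errors="coerce").dropna()
        if va.size < 2 or vb.size < 2:
            warnings.warn(f"feature {feature!r} has too few known values; "
                          "skipped", stacklevel=2)
            continue
        _, p = two_sample_ttest(va, vb, equal_var=False)
        rows.append({"feature": feature, "n_A": int(va.size),
                     "n_B": int(vb.size),
                     "summary_A": f"mean={va.mean():.3g}",
                     "summary_B": f"mean={vb.mean():.3g}",
                     "test": "welch_t", "p": p})
    return pd.DataFrame(rows, columns=["feature", "n_A", "n_B", "summary_A",
                                       "summary_B", "test", "p"])
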