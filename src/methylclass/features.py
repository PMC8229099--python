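"""Dual unsupervised CpG selection.

Two selectors run per cross-validation fold on the training portion and
their union over folds is retained:

* PCA selection — the CpGs with the largest absolute loadings on each of
  the leading principal components;
* LVHC filtering — drop low-variance CpGs, then break up highly
  correlated pairs keeping the higher-variance member.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .types import BetaMatrix, FeatureSet

__all__ = ["pca_component_select", "lvhc_select", "select_features"]


def _median_imputed(beta: BetaMatrix) -> pd.DataFrame:
    """Per-CpG median imputation of the matrix itself (unsupervised use)."""
    df = beta.data
    medians = df.median(axis=1)
    return df.T.fillna(medians).T if df.isna().any().any() else df


def pca_component_select(
    beta_sub: BetaMatrix,
    n_components: int = 15,
    top_per_component: int = 20,
) -> set[str]:
    """CpGs with the largest absolute PCA loadings.

    The sample x CpG matrix is median-imputed per CpG and mean-centred;
    for each of the first ``n_components`` principal components the
    ``top_per_component`` CpGs by absolute loading are taken, and the
    deduplicated union over components is returned.
    """
    if beta_sub.n_samples < 2:
        raise ValueError("PCA selection requires at least 2 samples")
    x = _median_imputed(beta_sub).to_numpy().T  # samples x CpGs
    max_rank = min(x.shape[0] - 1, x.shape[1])
    k = n_components
    if k > max_rank:
        warnings.warn(
            f"n_components={n_components} truncated to {max_rank}",
            stacklevel=2)
        k = max_rank
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x - x.mean(axis=0))
    loadings = pca.components_  # (k, n_cpgs)
    # zero-variance components carry arbitrary loadings; skip them
    informative = pca.explained_variance_ > 1e-12 * max(
        pca.explained_variance_[0], 1e-300)
    cpgs = np.asarray(beta_sub.cpg_ids)
    selected: set[str] = set()
    top = min(top_per_component, loadings.shape[1])
    for comp, keep in zip(loadings, informative):
        if not keep:
            continue
        idx = np.argsort(-np.abs(comp), kind="stable")[:top]
        selected.update(str(c) for c in cpgs[idx])
    return selected


def lvhc_select(
    beta_sub: BetaMatrix,
    var_threshold: float = 0.1,
    corr_threshold: float = 0.7,
) -> set[str]:
    """Survivors of the low-variance / high-correlation filter.

    CpGs with variance below ``var_threshold`` are removed.  The rest are
    scanned in descending-variance order (ties by CpG ID); a CpG is kept
    only if its absolute Pearson correlation with every already-kept CpG
    is <= ``corr_threshold``, so of any offending pair the lower-variance
    member is dropped.  Correlations use median-imputed values.
    """
    df = _median_imputed(beta_sub)
    variances = df.var(axis=1, ddof=1)
    candidates = variances[variances >= var_threshold]
    if candidates.empty:
        return set()
    order = sorted(candidates.index,
                   key=lambda c: (-candidates[c], c))
    sub = df.loc[order].to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(abs(corr[i, j]) <= corr_threshold for j in kept_idx):
            kept_idx.append(i)
    return {order[i] for i in kept_idx}


def select_features(
    beta: BetaMatrix,
    k_folds: int = 5,
    seed: int = 0,
    n_components: int = 15,
    top_per_component: int = 20,
    var_threshold: float = 0.1,
    corr_threshold: float = 0.7,
) -> FeatureSet:
    """Union of both selectors over ``k_folds`` training splits.

    Samples are partitioned into ``k_folds`` seeded folds; for each fold
    both selectors run on the other ``k_folds - 1`` folds and every CpG
    either selector picks in any fold joins the final set, with
    per-(method, fold) provenance recorded.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if beta.n_samples < k_folds:
        raise ValueError("need at least k_folds samples")
    provenance: dict[str, list[tuple[str, int]]] = {}
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    sample_ids = np.asarray(beta.sample_ids)
    for fold, (train_idx, _) in enumerate(splitter.split(sample_ids)):
        train = beta.subset_samples(sample_ids[train_idx])
        picked_pca = pca_component_select(train, n_components,
                                          top_per_component)
        picked_lvhc = lvhc_select(train, var_threshold, corr_threshold)
        for cpg in picked_pca:
            provenance.setdefault(cpg, []).append(("PCA", fold))
        for cpg in picked_lvhc:
            provenance.setdefault(cpg, []).append(("LVHC", fold))
    ordered = [c for c in beta.cpg_ids if c in provenance]
    return FeatureSet(ordered, provenance)
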