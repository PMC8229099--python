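"""Beta-matrix quality control.

Masks calls that fail the detection p-value cutoff, filters probes by
blacklist / autosomal membership / missingness, and flags outlier samples
from a classical MDS embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BetaMatrix

__all__ = [
    "FilterReport",
    "mask_low_confidence",
    "filter_probes",
    "detect_outliers_mds",
    "classical_mds",
]


@dataclass
class FilterReport:
    n_input_cpgs: int = 0
    n_masked_entries: int = 0
    n_removed_blacklist: int = 0
    n_removed_nonautosomal: int = 0
    n_removed_missingness: int = 0
    n_output_cpgs: int = 0
    outlier_sample_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        removed = (self.n_removed_blacklist + self.n_removed_nonautosomal
                   + self.n_removed_missingness)
        if self.n_output_cpgs != self.n_input_cpgs - removed:
            raise ValueError("FilterReport counts are inconsistent")
        for name in ("n_input_cpgs", "n_masked_entries", "n_removed_blacklist",
                     "n_removed_nonautosomal", "n_removed_missingness",
                     "n_output_cpgs"):
            if getattr(self, name) < 0:
                raise ValueError(f"FilterReport.{name} negative")

    def to_dict(self) -> dict:
        return {
            "n_input_cpgs": self.n_input_cpgs,
            "n_masked_entries": self.n_masked_entries,
            "n_removed_blacklist": self.n_removed_blacklist,
            "n_removed_nonautosomal": self.n_removed_nonautosomal,
            "n_removed_missingness": self.n_removed_missingness,
            "n_output_cpgs": self.n_output_cpgs,
            "outlier_sample_ids": self.outlier_sample_ids,
        }


class EmptyMatrixError(ValueError):
    """Raised when filtering removes every CpG; carries the report."""

    def __init__(self, report: FilterReport):
        super().__init__("probe filtering removed every CpG")
        self.report = report


def mask_low_confidence(beta: BetaMatrix, detection_p, alpha: float = 0.05,
                        ) -> BetaMatrix:
    """Blank beta values whose detection p-value is >= ``alpha``.

    A call passes only when ``p < alpha`` (p equal to the cutoff fails).
    Idempotent; non-failing entries are returned unchanged.
    """
    p = detection_p.to_numpy() if isinstance(detection_p, pd.DataFrame) \
        else np.asarray(detection_p, float)
    if p.shape != beta.values.shape:
        raise ValueError(
            f"detection_p shape {p.shape} != beta shape {beta.values.shape}")
    if isinstance(detection_p, pd.DataFrame):
        if (list(detection_p.index) != beta.cpg_ids
                or list(detection_p.columns) != beta.sample_ids):
            raise ValueError("detection_p index/columns do not match beta")
    values = beta.values.copy()
    values[p >= alpha] = np.nan
    return BetaMatrix(pd.DataFrame(values, index=beta.cpg_ids,
                                   columns=beta.sample_ids))


def filter_probes(
    beta: BetaMatrix,
    blacklist=(),
    autosomal_ids=None,
    max_missing_frac: float = 0.10,
) -> tuple[BetaMatrix, FilterReport]:
    """Drop blacklisted, non-autosomal and high-missingness CpGs.

    Removal categories are attributed in the order blacklist ->
    non-autosomal -> missingness.  A CpG with missing fraction strictly
    above ``max_missing_frac`` is removed; exactly at the threshold it is
    retained.  Surviving values are never altered.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    blacklist = set(blacklist)
    report = FilterReport(n_input_cpgs=beta.n_cpgs)

    index = beta.data.index
    in_black = index.isin(blacklist)
    report.n_removed_blacklist = int(in_black.sum())
    keep = ~in_black

    if autosomal_ids is not None:
        autosomal = index.isin(set(autosomal_ids))
        report.n_removed_nonautosomal = int((keep & ~autosomal).sum())
        keep &= autosomal

    miss_frac = beta.data.isna().mean(axis=1).to_numpy()
    too_missing = miss_frac > max_missing_frac
    report.n_removed_missingness = int((keep & too_missing).sum())
    keep &= ~too_missing

    report.n_output_cpgs = int(keep.sum())
    report.validate()
    if report.n_output_cpgs == 0:
        raise EmptyMatrixError(report)
    return BetaMatrix(beta.data.loc[keep].copy()), report


def _pairwise_euclidean(values: np.ndarray) -> np.ndarray:
    """Sample-by-sample Euclidean distances, missing handled pairwise.

    Squared distances are averaged over the coordinates observed in both
    samples and rescaled to the full dimensionality, so samples with more
    missingness remain comparable.
    """
    n_cpgs, n = values.shape
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    sq = filled ** 2
    # pairwise counts and sums over shared observed coordinates
    shared = obs.T.astype(float) @ obs.astype(float)
    cross = filled.T @ filled
    sum_sq_i = sq.T @ obs.astype(float)
    d2 = sum_sq_i + sum_sq_i.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, d2 / shared * n_cpgs, 0.0)
    d2 = np.clip(d2, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def classical_mds(dist: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def detect_outliers_mds(beta: BetaMatrix, n_dims: int = 2,
                        mad_factor: float = 5.0) -> list[str]:
    """Flag samples far from the bulk in a classical MDS embedding.

    A sample is an outlier when its embedding distance from the
    coordinate-wise median exceeds the median of those distances by more
    than ``mad_factor`` times their median absolute deviation.
    """
    if beta.n_samples < 3:
        raise ValueError("outlier detection requires at least 3 samples")
    coords = classical_mds(_pairwise_euclidean(beta.values), n_dims)
    center = np.median(coords, axis=0)
    dists = np.sqrt(((coords - center) ** 2).sum(axis=1))
    deviations = dists - np.median(dists)
    mad = np.median(np.abs(deviations))
    # numerical-noise floor so identical samples are never flagged
    floor = 1e-8 * np.sqrt(beta.n_cpgs)
    cutoff = max(mad_factor * mad, floor) if np.isfinite(mad_factor) \
        else np.inf
    flagged = deviations > cutoff
    return [sid for sid, f in zip(beta.sample_ids, flagged) if f]
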