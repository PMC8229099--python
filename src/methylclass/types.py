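"""Core data containers shared by every pipeline stage.

The central structure is :class:`BetaMatrix`, a CpG-by-sample matrix of
methylation fractions (beta values) in ``[0, 1]`` with ``NaN`` marking
missing calls.  :class:`SampleSheet` carries per-sample annotation:
subtype labels, clinical covariates, mutation flags and survival fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "SampleSheet", "MUTATION_COLUMNS", "SHEET_COLUMNS"]

MUTATION_COLUMNS = ["CEBPA", "FLT3", "NPM1", "WT1"]

SHEET_COLUMNS = [
    "sample_id",
    "true_subtype",
    "reported_subtype",
    "timepoint",
    "age",
    "sex",
    *MUTATION_COLUMNS,
    "rfs_time",
    "rfs_event",
    "os_time",
    "os_event",
]


@dataclass
class BetaMatrix:
    """CpG x sample matrix of beta values.

    Parameters
    ----------
    data:
        DataFrame with CpG IDs as the index and sample IDs as columns.
        Entries are floats in ``[0, 1]``; missing calls are ``NaN``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("BetaMatrix.data must be a pandas DataFrame")
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate CpG IDs in BetaMatrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in BetaMatrix")
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    # -- accessors ---------------------------------------------------------
    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """(n_cpgs, n_samples) float array with NaN for missing."""
        return self.data.to_numpy()

    @property
    def n_cpgs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- manipulation ------------------------------------------------------
    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        cpg_ids = list(cpg_ids)
        missing = set(cpg_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown CpG IDs: {sorted(missing)[:5]}...")
        return BetaMatrix(self.data.loc[cpg_ids].copy())

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)[:5]}...")
        return BetaMatrix(self.data[sample_ids].copy())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.data.copy())

    def missing_fraction(self) -> pd.Series:
        """Per-CpG fraction of missing entries."""
        return self.data.isna().mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleSheet:
    """Per-sample annotation table.

    Columns (see :data:`SHEET_COLUMNS`): subtype labels (``reported_subtype``
    may be ``"undefined"``), ``timepoint`` in {diagnosis, relapse}, age in
    years, sex, mutation flags coded 1/0/NaN (NaN = unknown) and the
    relapse-free / overall survival time and event fields.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("sample sheet requires a 'sample_id' column")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in sample sheet")
        for col in ("rfs_time", "os_time"):
            if col in self.data.columns:
                t = pd.to_numeric(self.data[col], errors="coerce")
                if (t.dropna() < 0).any():
                    raise ValueError(f"{col} must be non-negative")
        for col in ("rfs_event", "os_event"):
            if col in self.data.columns:
                e = pd.to_numeric(self.data[col], errors="coerce").dropna()
                if not e.isin([0, 1]).all():
                    raise ValueError(f"{col} must be binary")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def loc_samples(self, sample_ids) -> "SampleSheet":
        sub = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(sub)

    def column(self, name: str, sample_ids=None) -> pd.Series:
        df = self.data.set_index("sample_id")
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        return df[name]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FeatureSet:
    """Selected CpG IDs with provenance.

    ``provenance`` maps each member CpG to the list of ``(method, fold)``
    pairs that selected it, with ``method`` in ``{"PCA", "LVHC"}``.
    """

    cpg_ids: list[str]
    provenance: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("duplicate CpG IDs in FeatureSet")
        for cpg in self.cpg_ids:
            if not self.provenance.get(cpg):
                raise ValueError(f"FeatureSet member {cpg} lacks provenance")

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def __contains__(self, cpg: str) -> bool:
        return cpg in self.provenance

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cpg in self.cpg_ids:
            prov = self.provenance[cpg]
            methods = ",".join(sorted({m for m, _ in prov}))
            folds = ",".join(str(f) for _, f in sorted(set(prov)))
            rows.append({"cpg_id": cpg, "methods": methods, "folds": folds})
        return pd.DataFrame(rows, columns=["cpg_id", "methods", "folds"])
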