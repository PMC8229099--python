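"""Tab-separated text I/O for every artifact the pipeline reads or writes.

Dialect: beta and detection-p matrices are TSV with CpG IDs in the first
column, sample IDs in the header row and ``NA`` for missing entries.  The
sample sheet is a TSV with the documented column names.  Truth maps are
two-column TSVs (subtype, cpg_id).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BetaMatrix, FeatureSet, SampleSheet

NA_REP = "NA"
FLOAT_FMT = "%.6g"


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.data.to_csv(path, sep="\t", na_rep=NA_REP, index_label="cpg_id",
                     float_format=FLOAT_FMT)


def read_beta_matrix(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cpg_id", na_values=[NA_REP])
    return BetaMatrix(df)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a generic CpG x sample numeric matrix (e.g. detection p)."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, index_label="cpg_id",
              float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id", na_values=[NA_REP])


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", na_rep=NA_REP, index=False,
                      float_format=FLOAT_FMT)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    return SampleSheet(df)


def write_truth_map(truth: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("subtype\tcpg_id\n")
        for subtype in sorted(truth):
            for cpg in truth[subtype]:
                fh.write(f"{subtype}\t{cpg}\n")


def read_truth_map(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    truth: dict[str, list[str]] = {}
    for subtype, grp in df.groupby("subtype", sort=True):
        truth[str(subtype)] = list(grp["cpg_id"])
    return truth


def write_feature_set(fs: FeatureSet, path) -> None:
    fs.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_set(path) -> FeatureSet:
    df = pd.read_csv(path, sep="\t")
    provenance: dict[str, list[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        methods = str(row["methods"]).split(",")
        folds = [int(f) for f in str(row["folds"]).split(",")]
        pairs = [(m, f) for m in methods for f in folds]
        provenance[row["cpg_id"]] = pairs
    return FeatureSet(list(df["cpg_id"]), provenance)


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_key_values(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            if isinstance(value, (list, tuple, set, np.ndarray)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}\t{value}\n")
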