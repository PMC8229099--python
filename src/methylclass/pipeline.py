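"""End-to-end orchestration of the analysis stages.

Every stage reads and writes only declared files under the run
directory; a manifest records parameters, the root seed, per-stage
derived seeds and input checksums so any stage can be re-run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, differential, features, heterogeneity, io
from . import preprocess as prep
from . import simulate as sim
from . import survival as surv
from .config import PipelineConfig
from .types import BetaMatrix, SampleSheet

logger = logging.getLogger("methylclass")

STAGES = ["simulate", "preprocess", "features", "train", "predict",
          "permtest", "diffmeth", "cluster", "survival"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_known(sheet: SampleSheet, test_fraction: float, seed: int):
    """Stratified train/test split of diagnostic samples of known subtype.

    Classes with a single sample go entirely to the training set.
    """
    from sklearn.model_selection import train_test_split

    df = sheet.data
    known = df[(df["timepoint"] == "diagnosis")
               & (df["reported_subtype"] != "undefined")]
    counts = known["reported_subtype"].value_counts()
    singles = counts[counts < 2].index
    single_ids = known[known["reported_subtype"].isin(singles)]["sample_id"]
    rest = known[~known["reported_subtype"].isin(singles)]
    train_ids, test_ids = train_test_split(
        rest["sample_id"].to_numpy(), test_size=test_fraction,
        stratify=rest["reported_subtype"].to_numpy(), random_state=seed)
    return list(train_ids) + list(single_ids), list(test_ids)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order, writing artifacts + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {},
                      "seed": config.seed}

    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    try:
        _run_stages(config, out, manifest)
    except Exception as err:  # keep partial outputs, name the stage
        manifest["failed_stage"] = getattr(err, "_stage", "unknown")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out


def _record(manifest, stage, out: Path, files: list[str], seed=None):
    entry = {"files": {f: _checksum(out / f) for f in files}}
    if seed is not None:
        entry["seed"] = seed
    manifest["stages"][stage] = entry


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    beta = sheet = None
    truth = {}
    detection = None

    def fail(stage, err):
        err._stage = stage
        return err

    # ---- simulate --------------------------------------------------------
    if config.do_simulate:
        stage = "simulate"
        try:
            seed = stage_seed(config.seed, stage)
            sizes = config.subtype_sizes_dict()
            sim_config = sim.SimulationConfig(
                n_cpgs=config.n_cpgs,
                **({"subtype_sizes": sizes} if sizes else {}),
                n_signature_cpgs=config.n_signature_cpgs,
                effect_delta=config.effect_delta,
                noise_sd=config.noise_sd,
                n_undefined=config.n_undefined,
                n_relapse=config.n_relapse,
                n_outcome_cpgs=config.n_outcome_cpgs,
                outcome=sim.OutcomeConfig(config.baseline_hazard,
                                          config.hazard_ratio,
                                          config.censor_rate),
                seed=seed,
            )
            beta, sheet, truth = sim.simulate_cohort(sim_config)
            beta, detection = sim.inject_missingness(
                beta, config.missing_rate, config.detection_fail_rate,
                seed=seed + 1)
            io.write_beta_matrix(beta, out / "beta.tsv")
            io.write_matrix(detection, out / "detection_p.tsv")
            io.write_sample_sheet(sheet, out / "sample_sheet.tsv")
            io.write_truth_map(truth, out / "truth.tsv")
            _record(manifest, stage, out,
                    ["beta.tsv", "detection_p.tsv", "sample_sheet.tsv",
                     "truth.tsv"], seed)
            logger.info("simulate: %d CpGs x %d samples",
                        beta.n_cpgs, beta.n_samples)
        except Exception as err:
            raise fail(stage, err)
    else:
        if config.beta_path:
            beta = io.read_beta_matrix(config.beta_path)
            manifest["inputs"] = {
                "beta": _checksum(Path(config.beta_path))}
        if config.sheet_path:
            sheet = io.read_sample_sheet(config.sheet_path)
        if config.detection_p_path:
            detection = io.read_matrix(config.detection_p_path)

    # ---- preprocess ------------------------------------------------------
    if config.do_preprocess and beta is not None:
        stage = "preprocess"
        try:
            if detection is not None:
                beta = prep.mask_low_confidence(beta, detection,
                                                config.detection_alpha)
            blacklist = (io.read_id_list(config.blacklist_path)
                         if config.blacklist_path else ())
            autosomal = (io.read_id_list(config.autosomal_path)
                         if config.autosomal_path else None)
            beta, report = prep.filter_probes(
                beta, blacklist, autosomal, config.max_missing_frac)
            report.outlier_sample_ids = prep.detect_outliers_mds(
                beta, mad_factor=config.mds_mad_factor)
            io.write_beta_matrix(beta, out / "beta_filtered.tsv")
            io.write_key_values(report.to_dict(), out / "filter_report.tsv")
            for key, value in report.to_dict().items():
                logger.info("preprocess: %s = %s", key, value)
            _record(manifest, stage, out,
                    ["beta_filtered.tsv", "filter_report.tsv"])
        except Exception as err:
            raise fail(stage, err)

    if beta is None or sheet is None:
        return

    # ---- feature selection ----------------------------------------------
    feature_set = None
    if config.do_features:
        stage = "features"
        try:
            seed = stage_seed(config.seed, stage)
            feature_set = features.select_features(
                beta, k_folds=config.fs_k_folds, seed=seed,
                n_components=config.n_components,
                top_per_component=config.top_per_component,
                var_threshold=config.var_threshold,
                corr_threshold=config.corr_threshold)
            io.write_feature_set(feature_set, out / "features.tsv")
            _record(manifest, stage, out, ["features.tsv"], seed)
            logger.info("features: %d CpGs selected", len(feature_set))
        except Exception as err:
            raise fail(stage, err)

    if feature_set is None:
        return
    beta_fs = beta.subset_cpgs(feature_set.cpg_ids)

    df = sheet.data
    known_mask = ((df["timepoint"] == "diagnosis")
                  & (df["reported_subtype"] != "undefined"))
    known_ids = list(df.loc[known_mask, "sample_id"])
    labels = sheet.column("reported_subtype", known_ids)

    # ---- train -----------------------------------------------------------
    model = None
    report = None
    if config.do_train:
        stage = "train"
        try:
            seed = stage_seed(config.seed, stage)
            train_ids, test_ids = _split_known(sheet, config.test_fraction,
                                               seed)
            beta_train = beta_fs.subset_samples(train_ids)
            beta_test = beta_fs.subset_samples(test_ids)
            y_train = sheet.column("reported_subtype", train_ids)
            y_test = sheet.column("reported_subtype", test_ids)
            bank = classify.default_model_bank(
                small=config.model_grid == "small")
            report = classify.nested_cv_select(
                beta_train, y_train, bank, outer_k=config.outer_k,
                inner_k=config.inner_k, seed=seed)
            best_spec = next(s for s in bank
                             if s.family == report.best_family)
            model = classify.fit_final(beta_train, y_train, best_spec,
                                       seed=seed)
            preds = classify.predict_subtypes(model, beta_test)
            evaluation = classify.evaluate_predictions(
                preds["label"], y_test, sorted(set(labels)))
            report.confusion = evaluation.confusion
            report.per_class = evaluation.per_class
            report.accuracy = evaluation.accuracy

            report.summary().to_csv(out / "model_selection.tsv", sep="\t",
                                    index=False)
            evaluation.confusion.to_csv(out / "confusion.tsv", sep="\t")
            evaluation.per_class.to_csv(out / "per_class_metrics.tsv",
                                        sep="\t", index=False)
            preds.to_csv(out / "test_predictions.tsv", sep="\t", index=False)
            (out / "train_summary.txt").write_text(
                f"best_family\t{report.best_family}\n"
                f"test_accuracy\t{evaluation.accuracy:.4f}\n")
            _record(manifest, stage, out,
                    ["model_selection.tsv", "confusion.tsv",
                     "per_class_metrics.tsv", "test_predictions.tsv",
                     "train_summary.txt"], seed)
            logger.info("train: best=%s test accuracy=%.3f",
                        report.best_family, evaluation.accuracy)
            # refit on every known sample for downstream prediction
            model = classify.fit_final(
                beta_fs.subset_samples(known_ids), labels, best_spec,
                seed=seed, params=model.chosen_params)
        except Exception as err:
            raise fail(stage, err)

    # ---- predict undefined ----------------------------------------------
    predicted_map: dict[str, str] = {}
    if config.do_predict and model is not None:
        stage = "predict"
        try:
            undef_ids = list(df.loc[(df["timepoint"] == "diagnosis")
                                    & (df["reported_subtype"] == "undefined"),
                                    "sample_id"])
            if undef_ids:
                preds = classify.predict_subtypes(
                    model, beta_fs.subset_samples(undef_ids))
                preds.to_csv(out / "undefined_predictions.tsv", sep="\t",
                             index=False)
                predicted_map = dict(zip(preds["sample_id"], preds["label"]))
                _record(manifest, stage, out, ["undefined_predictions.tsv"])
        except Exception as err:
            raise fail(stage, err)

    # ---- permutation test ------------------------------------------------
    if config.do_permtest and model is not None:
        stage = "permtest"
        try:
            seed = stage_seed(config.seed, stage)
            spec = classify.ModelSpec(
                model.ensemble.spec.family,
                {k: [v] for k, v in model.chosen_params.items()}
                or {"dummy": [None]})
            p = classify.permutation_test(
                beta_fs.subset_samples(known_ids), labels, spec,
                n_permutations=config.n_permutations,
                outer_k=config.outer_k, inner_k=config.inner_k, seed=seed)
            (out / "permutation.tsv").write_text(
                f"n_permutations\t{config.n_permutations}\np\t{p:.6g}\n")
            _record(manifest, stage, out, ["permutation.tsv"], seed)
        except Exception as err:
            raise fail(stage, err)

    # ---- differential methylation ---------------------------------------
    dm_labels = pd.Series(
        [predicted_map.get(s, r) for s, r in zip(df["sample_id"],
                                                 df["reported_subtype"])],
        index=df["sample_id"])
    diag_all = df["timepoint"] == "diagnosis"
    dm_ids = [s for s, d in zip(df["sample_id"], diag_all)
              if d and dm_labels[s] != "undefined"]
    if config.do_diffmeth:
        stage = "diffmeth"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                dm = differential.one_vs_rest_dm(
                    beta_fs.subset_samples(known_ids), labels,
                    alpha=config.dm_alpha, min_group=config.min_group)
            dm.to_frame().to_csv(out / "differential.tsv", sep="\t",
                                 index=False)
            _record(manifest, stage, out, ["differential.tsv"])
        except Exception as err:
            raise fail(stage, err)

    # ---- heterogeneity clustering ---------------------------------------
    if config.do_cluster:
        stage = "cluster"
        try:
            counts = pd.Series([dm_labels[s] for s in dm_ids]).value_counts()
            target = counts.index[0] if len(counts) else None
            if target is not None and counts.iloc[0] >= 4:
                ids = [s for s in dm_ids if dm_labels[s] == target]
                assignment = heterogeneity.hier_cluster(
                    beta_fs.subset_samples(ids), k=2)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    assoc = heterogeneity.associate_clusters(
                        assignment, sheet.loc_samples(ids))
                pd.DataFrame(
                    {"sample_id": list(assignment.assignment),
                     "cluster": list(assignment.assignment.values())}
                ).to_csv(out / "clusters.tsv", sep="\t", index=False)
                assoc.to_csv(out / "cluster_associations.tsv", sep="\t",
                             index=False)
                _record(manifest, stage, out,
                        ["clusters.tsv", "cluster_associations.tsv"])
        except Exception as err:
            raise fail(stage, err)

    # ---- survival --------------------------------------------------------
    if config.do_survival:
        stage = "survival"
        try:
            if config.survival_subtypes:
                targets = config.survival_subtypes.split(",")
            else:
                counts = pd.Series(list(labels)).value_counts()
                targets = list(counts[counts >= 10].index)
            for subtype in targets:
                safe = "".join(ch if ch.isalnum() else "_"
                               for ch in subtype)
                try:
                    grouping, cox = surv.run_survival_stage(
                        beta_fs, sheet, subtype,
                        include_predicted=bool(predicted_map),
                        predicted=predicted_map,
                        alpha=config.surv_alpha, top_k=config.surv_top_k)
                except ValueError as err:
                    logger.warning("survival %s skipped: %s", subtype, err)
                    continue
                grouping.selected.to_csv(
                    out / f"survival_{safe}_cpgs.tsv", sep="\t", index=False)
                pd.DataFrame({
                    "sample_id": list(grouping.groups),
                    "group": list(grouping.groups.values()),
                }).to_csv(out / f"survival_{safe}_groups.tsv", sep="\t",
                          index=False)
                summary_rows = []
                for ep, (chi2, p) in grouping.logrank.items():
                    summary_rows.append({"endpoint": ep, "chi2": chi2,
                                         "logrank_p": p})
                    for label, curve in grouping.km[ep].items():
                        curve.to_csv(
                            out / f"survival_{safe}_{ep}_{label}_km.tsv",
                            sep="\t", index=False)
                    if ep in cox:
                        cox[ep].to_frame().to_csv(
                            out / f"survival_{safe}_{ep}_cox.tsv",
                            sep="\t", index=False)
                pd.DataFrame(summary_rows).to_csv(
                    out / f"survival_{safe}_tests.tsv", sep="\t", index=False)
            manifest["stages"]["survival"] = {"subtypes": targets}
        except Exception as err:
            raise fail(stage, err)
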