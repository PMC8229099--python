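"""Synthetic benchmark reproductions of the classifier's headline behavior.

``t1``: end-to-end feature selection -> nested-CV model selection ->
final fit on a stratified 66/33 split of a default synthetic cohort with
strong planted subtype signatures; reports held-out test accuracy.

``t2``: 1000-label-permutation validation of the selected model on the
same cohort, ``p = (C + 1) / (B + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import classify
from .features import select_features
from .pipeline import _split_known, stage_seed
from .simulate import SimulationConfig, inject_missingness, simulate_cohort
from .types import BetaMatrix, SampleSheet


@dataclass
class BenchmarkResult:
    accuracy: float
    best_family: str
    chosen_params: dict
    n_test: int
    n_train: int
    n_features: int
    beta_fs: BetaMatrix
    sheet: SampleSheet


def default_benchmark_config(seed: int) -> SimulationConfig:
    """Default cohort: 8 subtypes at the standard diagnostic frequencies,
    50 signature CpGs each, delta-beta 0.4, noise 0.05."""
    return SimulationConfig(n_cpgs=4000, n_signature_cpgs=50,
                            effect_delta=0.4, noise_sd=0.05,
                            n_undefined=24, seed=seed)


def run_t1(seed: int) -> BenchmarkResult:
    """Test-set accuracy of the best nested-CV-selected classifier."""
    sim_seed = stage_seed(seed, "benchmark-simulate")
    config = default_benchmark_config(sim_seed)
    beta, sheet, _ = simulate_cohort(config)
    beta, _ = inject_missingness(beta, missing_rate=0.05,
                                 detection_fail_rate=0.0,
                                 seed=stage_seed(seed, "benchmark-missing"))

    fs = select_features(beta, k_folds=5,
                         seed=stage_seed(seed, "benchmark-features"))
    beta_fs = beta.subset_cpgs(fs.cpg_ids)

    split_seed = stage_seed(seed, "benchmark-split") % (2**31)
    train_ids, test_ids = _split_known(sheet, test_fraction=1 / 3,
                                       seed=split_seed)
    beta_train = beta_fs.subset_samples(train_ids)
    beta_test = beta_fs.subset_samples(test_ids)
    y_train = sheet.column("reported_subtype", train_ids)
    y_test = sheet.column("reported_subtype", test_ids)

    bank = classify.default_model_bank()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = classify.nested_cv_select(
            beta_train, y_train, bank, outer_k=5, inner_k=3,
            seed=stage_seed(seed, "benchmark-cv") % (2**31))
        best_spec = next(s for s in bank if s.family == report.best_family)
        model = classify.fit_final(
            beta_train, y_train, best_spec,
            seed=stage_seed(seed, "benchmark-fit") % (2**31))
        preds = classify.predict_subtypes(model, beta_test)
        evaluation = classify.evaluate_predictions(
            preds["label"], y_test, sorted(set(y_train) | set(y_test)))
    return BenchmarkResult(
        accuracy=evaluation.accuracy,
        best_family=report.best_family,
        chosen_params=model.chosen_params,
        n_test=len(test_ids),
        n_train=len(train_ids),
        n_features=len(fs),
        beta_fs=beta_fs,
        sheet=sheet,
    )


def run_t2(seed: int, t1: BenchmarkResult | None = None,
           n_permutations: int = 1000) -> tuple[float, BenchmarkResult]:
    """Permutation p-value for the t1-selected model on the t1 cohort."""
    if t1 is None:
        t1 = run_t1(seed)
    df = t1.sheet.data
    known = df[(df["timepoint"] == "diagnosis")
               & (df["reported_subtype"] != "undefined")]
    beta_known = t1.beta_fs.subset_samples(known["sample_id"])
    labels = known["reported_subtype"]
    # reduced grid: the hyperparameters the t1 selection settled on
    spec = classify.ModelSpec(
        t1.best_family, {k: [v] for k, v in t1.chosen_params.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = classify.permutation_test(
            beta_known, labels, spec, n_permutations=n_permutations,
            outer_k=5, inner_k=3,
            seed=stage_seed(seed, "benchmark-perm") % (2**31))
    return p, t1
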