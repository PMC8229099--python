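"""Synthetic methylation cohorts with planted subtype and outcome structure.

The generator emits a beta matrix whose background CpGs follow a bimodal
beta distribution (a low-methylation and a high-methylation mode, as on
real arrays), plants per-subtype hyper/hypo-methylation signatures of a
configurable effect size, optionally plants a methylation group that
scales the hazard of the simulated survival outcomes, and can inject
missingness plus a matched detection p-value matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MUTATION_COLUMNS, SHEET_COLUMNS, BetaMatrix, SampleSheet

__all__ = [
    "BackgroundMix",
    "OutcomeConfig",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_outcomes",
    "inject_missingness",
]

#: diagnostic sample counts per cytogenetic subtype used as generator defaults
DEFAULT_SUBTYPE_SIZES = {
    "NK": 30,
    "MLL": 25,
    "t(8;21)": 19,
    "inv(16)": 12,
    "mono7": 5,
    "t(15;17)": 4,
    "sole+8": 3,
    "3q21q26": 1,
}

OUTCOME_KEY = "__outcome__"


@dataclass
class BackgroundMix:
    """Two-component background for per-CpG baseline methylation.

    ``low_weight`` of CpGs sit at ``low_mode``, the rest at ``high_mode``;
    each CpG's baseline is drawn from a beta distribution centred on its
    mode with the given ``concentration``.  A ``bimodal_frac`` fraction of
    CpGs are instead variable across samples: each sample independently
    draws from one of the two modes, producing the high-variance bimodal
    CpGs that the variance filter targets.
    """

    low_mode: float = 0.1
    high_mode: float = 0.85
    low_weight: float = 0.5
    concentration: float = 50.0
    bimodal_frac: float = 0.0

    def validate(self) -> None:
        for name in ("low_mode", "high_mode", "low_weight", "bimodal_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"background_mix.{name} must be in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("background_mix.concentration must be positive")


@dataclass
class OutcomeConfig:
    baseline_hazard: float = 0.02
    hazard_ratio: float = 1.0
    censor_rate: float = 0.2

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    n_cpgs: int = 5000
    subtype_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SIZES))
    n_signature_cpgs: int = 50
    effect_delta: float = 0.4
    background_mix: BackgroundMix = field(default_factory=BackgroundMix)
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    detection_fail_rate: float = 0.0
    n_undefined: int = 24
    n_relapse: int = 0
    n_outcome_cpgs: int = 0
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cpgs <= 0:
            raise ValueError("n_cpgs must be positive")
        if not self.subtype_sizes:
            raise ValueError("subtype_sizes must not be empty")
        if any(v < 0 for v in self.subtype_sizes.values()):
            raise ValueError("subtype sizes must be >= 0")
        if self.n_signature_cpgs < 0 or self.n_outcome_cpgs < 0:
            raise ValueError("signature CpG counts must be >= 0")
        active = sum(1 for v in self.subtype_sizes.values() if v > 0)
        needed = active * self.n_signature_cpgs + self.n_outcome_cpgs
        if needed > self.n_cpgs:
            raise ValueError(
                f"{needed} signature CpGs requested but only "
                f"{self.n_cpgs} CpGs simulated")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ValueError("effect_delta must be in [0, 1]")
        for name in ("missing_rate", "detection_fail_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_undefined < 0 or self.n_relapse < 0:
            raise ValueError("sample counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.background_mix.validate()
        self.outcome.validate()


def _draw_baselines(rng, mix: BackgroundMix, modes: np.ndarray) -> np.ndarray:
    """Per-CpG baseline beta values given each CpG's mode assignment."""
    c = mix.concentration
    means = np.where(modes == 0, mix.low_mode, mix.high_mode)
    a = np.clip(means * c, 1e-3, None)
    b = np.clip((1.0 - means) * c, 1e-3, None)
    return rng.beta(a, b)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, dict[str, list[str]]]:
    """Generate a cohort with planted subtype signatures.

    Returns the beta matrix, the sample sheet, and the truth map from
    subtype to its planted signature CpG IDs (plus ``"__outcome__"`` when
    an outcome signature is planted).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = config.background_mix

    cpg_ids = [f"cg{i:08d}" for i in range(config.n_cpgs)]
    subtypes = [s for s, n in config.subtype_sizes.items() if n > 0]

    # --- samples ----------------------------------------------------------
    true_labels: list[str] = []
    reported: list[str] = []
    for s in subtypes:
        true_labels.extend([s] * config.subtype_sizes[s])
        reported.extend([s] * config.subtype_sizes[s])
    sizes = np.array([config.subtype_sizes[s] for s in subtypes], float)
    probs = sizes / sizes.sum()
    for _ in range(config.n_undefined):
        s = subtypes[rng.choice(len(subtypes), p=probs)]
        true_labels.append(s)
        reported.append("undefined")
    n_diag = len(true_labels)
    sample_ids = [f"S{i:04d}" for i in range(n_diag)]

    # --- CpG structure ----------------------------------------------------
    n_low = int(round(mix.low_weight * config.n_cpgs))
    modes = np.zeros(config.n_cpgs, dtype=int)
    modes[n_low:] = 1
    rng.shuffle(modes)
    variable = rng.random(config.n_cpgs) < mix.bimodal_frac
    baselines = _draw_baselines(rng, mix, modes)

    low_pool = [i for i in range(config.n_cpgs)
                if modes[i] == 0 and not variable[i]]
    high_pool = [i for i in range(config.n_cpgs)
                 if modes[i] == 1 and not variable[i]]
    rng.shuffle(low_pool)
    rng.shuffle(high_pool)

    def take(pool: list[int], k: int) -> list[int]:
        if len(pool) < k:
            raise ValueError("not enough background CpGs to host signatures")
        out = pool[:k]
        del pool[:k]
        return out

    # half hypermethylated (low baseline + delta), half hypo (high - delta)
    truth: dict[str, list[str]] = {}
    signature_idx: dict[str, tuple[list[int], list[int]]] = {}
    n_hyper = config.n_signature_cpgs // 2 + config.n_signature_cpgs % 2
    n_hypo = config.n_signature_cpgs // 2
    for s in subtypes:
        hyper = take(low_pool, n_hyper)
        hypo = take(high_pool, n_hypo)
        signature_idx[s] = (hyper, hypo)
        truth[s] = sorted(cpg_ids[i] for i in hyper + hypo)

    out_hyper = take(low_pool, config.n_outcome_cpgs // 2
                     + config.n_outcome_cpgs % 2)
    out_hypo = take(high_pool, config.n_outcome_cpgs // 2)
    if config.n_outcome_cpgs:
        truth[OUTCOME_KEY] = sorted(cpg_ids[i] for i in out_hyper + out_hypo)

    # --- beta values ------------------------------------------------------
    values = np.tile(baselines[:, None], (1, n_diag))
    if variable.any():
        n_var = int(variable.sum())
        var_modes = rng.random((n_var, n_diag)) >= mix.low_weight
        means = np.where(var_modes, mix.high_mode, mix.low_mode)
        c = mix.concentration
        values[variable, :] = rng.beta(np.clip(means * c, 1e-3, None),
                                       np.clip((1 - means) * c, 1e-3, None))

    labels_arr = np.array(true_labels)
    for s in subtypes:
        cols = labels_arr == s
        hyper, hypo = signature_idx[s]
        values[np.ix_(hyper, cols)] += config.effect_delta
        values[np.ix_(hypo, cols)] -= config.effect_delta

    outcome_group = rng.integers(0, 2, size=n_diag)
    if config.n_outcome_cpgs:
        grp = outcome_group == 1
        values[np.ix_(out_hyper, grp)] += config.effect_delta
        values[np.ix_(out_hypo, grp)] -= config.effect_delta

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    # --- relapse samples: noisy copies of random diagnostic samples -------
    relapse_of: list[int] = []
    if config.n_relapse:
        relapse_of = list(rng.choice(n_diag, size=config.n_relapse,
                                     replace=False))
        rel = values[:, relapse_of]
        if config.noise_sd > 0:
            rel = rel + rng.normal(0.0, config.noise_sd, size=rel.shape)
        values = np.concatenate([values, np.clip(rel, 0.0, 1.0)], axis=1)

    all_ids = list(sample_ids)
    timepoints = ["diagnosis"] * n_diag
    for j, src in enumerate(relapse_of):
        all_ids.append(f"{sample_ids[src]}_r")
        true_labels.append(true_labels[src])
        reported.append(reported[src])
        timepoints.append("relapse")
    outcome_group = np.concatenate(
        [outcome_group, outcome_group[relapse_of]]) if relapse_of \
        else outcome_group

    beta = BetaMatrix(pd.DataFrame(values, index=cpg_ids, columns=all_ids))

    # --- annotation -------------------------------------------------------
    n_total = len(all_ids)
    sheet = pd.DataFrame({
        "sample_id": all_ids,
        "true_subtype": true_labels,
        "reported_subtype": reported,
        "timepoint": timepoints,
        "age": np.round(rng.uniform(0, 18, size=n_total), 1),
        "sex": rng.choice(["F", "M"], size=n_total),
    })
    for gene in MUTATION_COLUMNS:
        flags = (rng.random(n_total) < 0.2).astype(float)
        flags[rng.random(n_total) < 0.25] = np.nan
        sheet[gene] = flags
    sheet["outcome_group"] = outcome_group.astype(int)

    sheet_obj = SampleSheet(sheet)
    sheet_obj = simulate_outcomes(
        sheet_obj,
        outcome_group,
        hazard_ratio=config.outcome.hazard_ratio,
        baseline_hazard=config.outcome.baseline_hazard,
        censor_rate=config.outcome.censor_rate,
        seed=rng.integers(0, 2**31 - 1),
    )
    sheet_obj.data = sheet_obj.data[SHEET_COLUMNS + ["outcome_group"]]
    return beta, sheet_obj, truth


def simulate_outcomes(
    sheet: SampleSheet,
    group_labels,
    hazard_ratio: float,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> SampleSheet:
    """Attach exponential RFS/OS outcomes whose hazard scales with group.

    Event times are exponential with hazard ``baseline_hazard *
    hazard_ratio**group``.  Censoring is administrative: follow-up ends at
    the horizon where a baseline-hazard subject survives with probability
    ``censor_rate``, so the baseline group is censored at that rate and
    higher-hazard groups proportionally less (independent of the event
    process).  ``censor_rate = 0`` means complete follow-up.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    group = np.asarray(group_labels)
    if group.shape[0] != len(sheet):
        raise ValueError("group_labels length must match sample sheet")
    if not np.isin(group, [0, 1]).all():
        raise ValueError("group_labels must be binary (0/1)")

    rng = np.random.default_rng(seed)
    hazards = baseline_hazard * np.power(hazard_ratio, group.astype(float))
    horizon = (np.inf if censor_rate == 0
               else -np.log(censor_rate) / baseline_hazard)
    df = sheet.data.copy()
    for prefix in ("rfs", "os"):
        times = rng.exponential(1.0 / hazards)
        censored = times > horizon
        obs = np.minimum(times, horizon)
        df[f"{prefix}_time"] = np.round(obs, 4)
        df[f"{prefix}_event"] = (~censored).astype(int)
    return SampleSheet(df)


def inject_missingness(
    beta: BetaMatrix,
    missing_rate: float,
    detection_fail_rate: float,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Blank a random fraction of entries and emit a detection-p matrix.

    Detection p-values are < 0.05 for passing entries and uniform on
    [0.05, 1] for the ``detection_fail_rate`` fraction that fail.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("detection_fail_rate", detection_fail_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = beta.values.copy()
    shape = values.shape
    if missing_rate > 0:
        values[rng.random(shape) < missing_rate] = np.nan
    detect = rng.uniform(0.0, 0.05, size=shape)
    fail = rng.random(shape) < detection_fail_rate
    detect[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
    out = BetaMatrix(pd.DataFrame(values, index=beta.cpg_ids,
                                  columns=beta.sample_ids))
    detect_df = pd.DataFrame(detect, index=beta.cpg_ids,
                             columns=beta.sample_ids)
    return out, detect_df
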