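"""Flat key-value pipeline configuration.

The config file is plain text, one ``key = value`` (or ``key<TAB>value``)
per line, ``#`` comments allowed.  Every CLI flag overrides the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig", "read_config_file"]

_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


@dataclass
class PipelineConfig:
    # paths
    out_dir: str = "run"
    beta_path: str = ""
    detection_p_path: str = ""
    sheet_path: str = ""
    blacklist_path: str = ""
    autosomal_path: str = ""
    # stage toggles
    do_simulate: bool = True
    do_preprocess: bool = True
    do_features: bool = True
    do_train: bool = True
    do_predict: bool = True
    do_permtest: bool = False
    do_diffmeth: bool = True
    do_cluster: bool = True
    do_survival: bool = True
    # simulate
    n_cpgs: int = 5000
    subtype_sizes: str = ""  # e.g. "NK:30,MLL:25"; empty = defaults
    n_signature_cpgs: int = 50
    effect_delta: float = 0.4
    noise_sd: float = 0.05
    missing_rate: float = 0.05
    detection_fail_rate: float = 0.01
    n_undefined: int = 24
    n_relapse: int = 0
    n_outcome_cpgs: int = 50
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.02
    censor_rate: float = 0.2
    # preprocess
    detection_alpha: float = 0.05
    max_missing_frac: float = 0.10
    mds_mad_factor: float = 5.0
    # feature selection
    fs_k_folds: int = 5
    n_components: int = 15
    top_per_component: int = 20
    var_threshold: float = 0.1
    corr_threshold: float = 0.7
    # classification
    model_grid: str = "full"  # full | small
    outer_k: int = 5
    inner_k: int = 3
    n_permutations: int = 1000
    test_fraction: float = 1 / 3
    # differential
    dm_alpha: float = 0.05
    min_group: int = 3
    # survival
    surv_alpha: float = 0.05
    surv_top_k: int = 50
    survival_subtypes: str = ""  # comma separated; empty = auto
    # global
    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_rate", "detection_fail_rate", "censor_rate",
                     "max_missing_frac", "detection_alpha", "dm_alpha",
                     "surv_alpha", "var_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        for name in ("n_cpgs", "fs_k_folds", "outer_k", "inner_k",
                     "n_permutations", "surv_top_k", "n_components",
                     "top_per_component"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.model_grid not in ("full", "small"):
            raise ValueError("model_grid must be 'full' or 'small'")

    def subtype_sizes_dict(self) -> dict[str, int] | None:
        if not self.subtype_sizes:
            return None
        out = {}
        for item in self.subtype_sizes.split(","):
            name, _, count = item.partition(":")
            out[name.strip()] = int(count)
        return out

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(value: str, target_type):
    value = value.strip()
    if target_type is bool:
        low = value.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"cannot parse boolean: {value!r}")
    if target_type is int:
        return int(value)
    if target_type is float:
        return float(value)
    return value


def read_config_file(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a flat key-value config file into a :class:`PipelineConfig`."""
    text = Path(path).read_text()
    known = {f.name: f.type for f in fields(PipelineConfig)}
    types = {f.name: type(getattr(PipelineConfig(), f.name))
             for f in fields(PipelineConfig)}
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, raw = line.partition("=")
        elif "\t" in line:
            key, _, raw = line.partition("\t")
        else:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key = key.strip()
        if key not in known:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        values[key] = _coerce(raw, types[key])
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    config = PipelineConfig(**values)
    config.validate()
    return config
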