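"""Run configuration: validated, serializable, with stable derived seeds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Unknown keys are rejected at load time; the config round-trips through
    YAML/JSON losslessly.  Stage seeds are derived by stable hashing of the
    stage name together with the master seed.
    """

    input_dir: str = ""
    out_dir: str = "run"
    reference_condition: str = "control"
    conditions: list = field(default_factory=lambda: ["control"])
    master_seed: int = 0

    # feature extraction
    smoothing: str = "gcv"

    # transforms
    boxcox_alpha: float = 0.01
    boxcox_keep: list = field(default_factory=list)
    stationarity_alpha: float = 0.05
    stationarity_min_fraction: float = 0.8
    stationarity_min_track_length: int = 30

    # population structure
    pca_variance_target: float = 0.85
    em_k_min: int = 2
    em_k_max: int = 8
    em_restarts: int = 10
    em_final_restarts: int = 100
    aic_penalty: str = "full"

    # feature selection
    en_l1_ratio: float = 0.5
    en_n_alphas: int = 100

    # granger
    lag_max: int = 10
    edge_min_fraction_05: float = 0.60
    edge_min_fraction_0001: float = 0.25
    test_form: str = "f"
    sign_method: str = "spearman"
    granger_pairs: list = field(default_factory=list)  # [[source, target], ...]
    chain: list = field(default_factory=list)

    # stage toggles
    run_subpopulations: bool = True
    run_selection: bool = True
    run_granger: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        blob = f"{stage}:{self.master_seed}".encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2 ** 31)
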