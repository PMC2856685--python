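"""Run configuration and report serialization.

The configuration is a flat, fully documented key set; unknown keys are
rejected outright so a typo cannot silently fall back to a default.  Every
artifact written carries the master seed and a hash of the configuration, so
two runs with the same config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .protocol import EvaluationReport

__all__ = ["RunConfig", "ConfigError", "load_config", "write_report", "read_report"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat configuration of a classification run."""

    expression: str = ""
    labels: str | None = None
    label_column: str | None = None
    sources: list[str] = field(default_factory=list)
    out_dir: str = "netkern_out"
    n_keep: int = 5000
    impute_k: int = 15
    max_missing_frac: float = 0.5
    normalized_laplacian: bool = False
    folds: int = 10
    inner_folds: int = 5
    repeats: int = 200
    seed: int = 0
    gamma_min: float = 1e-4
    gamma_max: float = 1e6
    gamma_points: int = 40
    rules: list[str] = field(default_factory=lambda: [
        "mean", "median", "weighted", "scaled_weighted", "exhaustive",
        "nb", "lr", "lda"])
    transposed: bool = False

    def validate(self) -> None:
        if not self.expression:
            raise ConfigError("field 'expression': a path is required")
        if self.repeats < 1:
            raise ConfigError("field 'repeats': must be >= 1")
        if self.n_keep < 1:
            raise ConfigError("field 'n_keep': must be >= 1")
        if self.folds < 2 or self.inner_folds < 2:
            raise ConfigError("fields 'folds'/'inner_folds': must be >= 2")
        if not (0 < self.gamma_min < self.gamma_max):
            raise ConfigError("fields 'gamma_min'/'gamma_max': need 0 < min < max")
        if self.gamma_points < 1:
            raise ConfigError("field 'gamma_points': must be >= 1")

    def gamma_grid(self) -> np.ndarray:
        from .lssvm import default_gamma_grid
        return default_gamma_grid(self.gamma_points, self.gamma_min, self.gamma_max)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path: str) -> RunConfig:
    """Parse, fill defaults, and validate; unknown keys are an error."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def write_report(report: EvaluationReport, out_dir: str,
                 config: RunConfig | None = None) -> tuple[str, str]:
    """Write the full JSON report and the CSV summary; returns both paths.

    The summary has one row per model with mean AUC, standard deviation, the
    one-sided paired-t p-value against the baseline and -log10(p).
    """
    os.makedirs(out_dir, exist_ok=True)
    meta = {
        "master_seed": report.master_seed,
        "config_hash": None if config is None else config.config_hash(),
        "config": None if config is None else config.to_dict(),
    }
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump({"meta": meta, "report": report.to_dict()}, fh, indent=1)

    csv_path = os.path.join(out_dir, "summary.csv")
    frame = report.summary_frame()
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# master_seed={report.master_seed} "
                 f"config_hash={meta['config_hash']}\n")
        frame.to_csv(fh, index=False, float_format="%.6g")
    return json_path, csv_path


def read_report(json_path: str) -> EvaluationReport:
    with open(json_path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return EvaluationReport.from_dict(payload["report"])
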