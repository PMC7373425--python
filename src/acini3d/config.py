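"""Run configuration: input mode, paths, generator/clustering/selection params.

A config file is YAML mirroring RunConfig field-for-field; every default is
echoed into the run manifest so no silent defaults exist.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cluster_id import CutParams
from .errors import ConfigError
from .feature_extraction import DEFAULT_DIAMETER_MEAN, DEFAULT_DIAMETER_SD
from .synthetic_acini import SyntheticConfig

INPUT_MODES = ("synthetic", "canonical_csv", "supplementary_xlsx")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (exactly one input mode)."""

    input_mode: str = "synthetic"
    # canonical_csv mode
    cells_start_csv: str | None = None
    cells_end_csv: str | None = None
    outcomes_csv: str | None = None
    lineage_csv: str | None = None
    # supplementary_xlsx mode
    xlsx_start: str | None = None
    xlsx_end: str | None = None
    xlsx_labels: str | None = None
    column_map: dict = field(default_factory=lambda: {"x": "x", "y": "y", "z": "z"})
    label_column_map: dict = field(default_factory=lambda: {"cell_id": "label"})
    # synthetic mode
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # analysis parameters
    clustering: CutParams = field(default_factory=CutParams)
    contact_diameter_mean: float = DEFAULT_DIAMETER_MEAN
    contact_diameter_sd: float = DEFAULT_DIAMETER_SD
    fold_expansion_threshold: float = 4.0
    delta_window: float = 3.0
    n_top_features_mixed: int = 3
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ConfigError(
                f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}"
            )
        if self.input_mode == "canonical_csv" and not self.cells_start_csv:
            raise ConfigError("canonical_csv mode requires cells_start_csv")
        if self.input_mode == "supplementary_xlsx" and not self.xlsx_start:
            raise ConfigError("supplementary_xlsx mode requires xlsx_start")
        # exactly one input mode: reject paths belonging to another mode
        if self.input_mode == "synthetic" and (self.cells_start_csv or self.xlsx_start):
            raise ConfigError("synthetic mode must not set input file paths")
        if self.input_mode == "canonical_csv" and self.xlsx_start:
            raise ConfigError("canonical_csv mode must not set xlsx paths")
        if self.input_mode == "supplementary_xlsx" and self.cells_start_csv:
            raise ConfigError("supplementary_xlsx mode must not set csv paths")
        if self.outcomes_csv and self.lineage_csv:
            raise ConfigError("provide at most one of outcomes_csv / lineage_csv")
        self.synthetic.validate()
        self.clustering.validate()
        if self.delta_window <= 0:
            raise ConfigError("delta_window must be > 0")

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        if "synthetic" in data:
            kwargs["synthetic"] = SyntheticConfig.from_mapping(data.pop("synthetic") or {})
        if "clustering" in data:
            c = data.pop("clustering") or {}
            unknown = set(c) - {f.name for f in dataclasses.fields(CutParams)}
            if unknown:
                raise ConfigError(f"unknown clustering keys: {sorted(unknown)}")
            kwargs["clustering"] = CutParams(**c)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(data)
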