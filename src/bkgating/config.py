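"""Structured pipeline configuration (YAML-backed) and logging setup."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

log = logging.getLogger("bkgating")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    """Paths, seeds and constants shared by the CLI stages.

    The squash bounds and EF parameters default to the study's values
    (ΔVmax = 200 mV, Emax = 50 REU, top/bottom 10, 50 mV threshold); anchor
    residues default to synthetic-scale positions and should be set to the
    structure numbering of the real anchors (A316, V278) on real data.
    """

    workdir: str = "bkgating_run"
    seed: int = 0
    # synthetic-study scale
    n_positions: int = 200
    n_mutations: int = 473
    # squashing constants
    delta_v_max_mV: float = 200.0
    e_max_REU: float = 50.0
    # EF parameters
    ef_top_n: int = 10
    ef_threshold_mV: float = 50.0
    # anchors for covariance features (positions; None -> generator defaults)
    anchors: list[int] | None = None
    # curation
    primary_source_tag: str = "cui_lab"
    # position-numbering offset applied when reading external mutation tables
    # (e.g. to reconcile hslo1 vs mslo1 numbering); must be set explicitly
    numbering_offset: int = 0
    # modeling
    n_splits: int = 5
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.delta_v_max_mV <= 0 or self.e_max_REU <= 0:
            raise ValueError("squash constants must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @property
    def paths(self) -> dict[str, Path]:
        w = Path(self.workdir)
        return {
            "workdir": w,
            "mutations_raw": w / "mutations_raw.csv",
            "curated": w / "curated.csv",
            "audit": w / "curation_audit.csv",
            "energies": w / "energies.csv",
            "dddg": w / "dddg.csv",
            "ensemble": w / "ensemble.pdb",
            "annotations": w / "annotations.csv",
            "dynamics": w / "dynamics.csv",
            "features": w / "features.csv",
            "model": w / "model.joblib",
            "model_meta": w / "model.json",
            "predictions": w / "predictions.csv",
            "report": w / "report.csv",
            "hotspots": w / "hotspots.csv",
            "hotspot_pdb": w / "hotspots.pdb",
        }
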