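"""YAML run configuration: schema validation and provenance stamping.

The configuration mirrors the module structure (backbone / train / eval /
embed / simulate sections).  Validation is strict — unknown keys are
rejected before any computation — and every command writes a provenance
JSON (config hash, seed, package versions) next to its outputs so any
artifact directory can be re-created from the command line.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .backbone import DEPTHS

__all__ = ["RunConfig", "load_config", "write_provenance"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BackboneSection(_Strict):
    sample_rate: int = 22050
    fine_tune_depth: str = "none"
    weights_path: str | None = None

    def model_post_init(self, _ctx):
        if self.fine_tune_depth not in DEPTHS:
            raise ValueError(f"fine_tune_depth must be one of {DEPTHS}")


class TrainSection(_Strict):
    window_tr: int = Field(70, ge=1)
    learning_rate: float = Field(1e-2, gt=0)
    kernel_size: int = Field(5, ge=1)
    weight_decay: float = Field(1e-4, ge=0)
    delta: float = Field(1e-4, ge=0)
    patience: int = Field(10, ge=1)
    batch_size: int = Field(1, ge=1)
    max_epochs: int = Field(100, ge=1)
    adam_eps: float = Field(1e-8, gt=0)
    train_fraction: float = Field(0.75, gt=0, lt=1)


class EvalSection(_Strict):
    window_tr: int = Field(70, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    method: str = "auto"


class EmbedSection(_Strict):
    mode: str = "scene"
    pre_pool: bool = False


class SimulateSection(_Strict):
    n_subjects: int = Field(1, ge=1)
    seasons: int = Field(1, ge=1)
    episodes_per_season: int = Field(5, ge=1)
    n_tr: int = Field(100, ge=1)
    n_targets: int = Field(10, ge=1)
    kernel_size: int = Field(3, ge=1)
    lag: int = Field(0, ge=0)
    noise_sigma: float = Field(1.5, ge=0)
    shared_mapping: bool = True
    plant_rank: int = Field(64, ge=1)


class RunConfig(_Strict):
    seed: int = 0
    verbosity: int = 1
    backbone: BackboneSection = BackboneSection()
    train: TrainSection = TrainSection()
    eval: EvalSection = EvalSection()
    embed: EmbedSection = EmbedSection()
    simulate: SimulateSection = SimulateSection()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def write_provenance(outdir: str | Path, config: RunConfig,
                     command: str, extra: dict | None = None) -> Path:
    """Drop a provenance.json sufficient to re-run the command."""
    import numpy
    import scipy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config.model_dump(), sort_keys=True)
    payload = {
        "command": command,
        "seed": config.seed,
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {"python": sys.version.split()[0],
                     "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
        **(extra or {}),
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=1))
    return path
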