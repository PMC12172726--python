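"""Study configuration: plain-YAML settings with explicit seeds throughout."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortParams
from .inference import SamplerConfig


@dataclass(frozen=True)
class StudyConfig:
    """Everything a full study run needs; regenerable from this + nothing else."""

    cohort: CohortParams = field(default_factory=CohortParams)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    n_nodes: int = 2000
    n_max: int = 80
    points_per_pad: int = 32
    include_optimized: bool = True
    include_group_main_only: bool = True
    focality_fraction: float = 0.01
    responses: tuple[str, ...] = ("mean_normfield", "mean_normal", "cv")
    out_dir: str = "study_output"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["responses"] = list(self.responses)
        return d


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Load a YAML config file; missing keys fall back to package defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    cohort = CohortParams(**raw.pop("cohort", {}))
    sampler = SamplerConfig(**raw.pop("sampler", {}))
    if "responses" in raw:
        raw["responses"] = tuple(raw["responses"])
    return StudyConfig(cohort=cohort, sampler=sampler, **raw)


def dump_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
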