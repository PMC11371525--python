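"""Run configuration: one YAML/JSON file, flat CLI overrides."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import platform
from typing import Any

import yaml

from .estimators import ForestSpec
from .evaluation import CVSpec
from .ingest import DEFAULT_MIN_STUDIES, EffectCategory, InvalidInputError
from .screening import DEFAULT_COVERAGE
from .selection import SelectionSpec


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one file."""

    features: str | None = None
    pods: str | None = None
    exposures: str | None = None
    output_dir: str = "podqsar_output"
    effect_category: str = EffectCategory.GENERAL_NONCANCER.value
    min_studies: int = DEFAULT_MIN_STUDIES
    feature_selection: bool = True
    estimator: str = "random_forest"
    coverage: float = DEFAULT_COVERAGE
    seed: int = 0
    forest: dict = dataclasses.field(default_factory=dict)
    selection: dict = dataclasses.field(default_factory=dict)
    cv: dict = dataclasses.field(default_factory=dict)

    def forest_spec(self) -> ForestSpec:
        return ForestSpec(**{"seed": self.seed, **self.forest})

    def selection_spec(self) -> SelectionSpec:
        return SelectionSpec(**{"seed": self.seed, **self.selection})

    def cv_spec(self) -> CVSpec:
        return CVSpec(**{"seed": self.seed, **self.cv})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path, **overrides) -> "RunConfig":
        """Read YAML (or JSON: valid YAML) and apply non-None overrides."""
        raw: dict[str, Any] = {}
        if path is not None:
            text = pathlib.Path(path).read_text()
            raw = yaml.safe_load(text) or {}
            if not isinstance(raw, dict):
                raise InvalidInputError(f"config {path} is not a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        EffectCategory(cfg.effect_category)  # validate
        if cfg.coverage <= 0 or cfg.coverage >= 1:
            raise InvalidInputError("coverage must be in (0, 1)")
        return cfg


def file_digest(path) -> str:
    """sha256 of an input file, for run provenance logs."""
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def provenance(config: RunConfig) -> dict[str, Any]:
    """Config echo + input digests + library versions, for the run log."""
    import numpy
    import pandas
    import sklearn

    from . import __version__

    digests = {}
    for key in ("features", "pods", "exposures"):
        p = getattr(config, key)
        if p and pathlib.Path(p).exists():
            digests[key] = file_digest(p)
    return {
        "config": config.to_dict(),
        "input_digests": digests,
        "seed": config.seed,
        "versions": {
            "podqsar": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def write_provenance(config: RunConfig, out_dir: pathlib.Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_info.json").write_text(
        json.dumps(provenance(config), indent=2, sort_keys=True)
    )
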