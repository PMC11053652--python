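"""Experiment configuration: one YAML file (or built-in defaults) drives the
whole generate → preprocess → augment → select → train → evaluate pipeline.

A single master seed fans out to per-stage seeds through a stable hash of the
stage name, so any stage can be re-run in isolation and reproduce itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig, SplitConfig
from .features import ForestConfig
from .io import Grid
from .models import CNNConfig, Hyperparams
from .preprocess import PreprocessConfig
from .synth import FourPLParams, NoiseModel, Peak, PeakLibrary, default_libraries

__all__ = ["ExperimentConfig", "ConfigError", "stage_seed", "MIXTURE_CONDITIONS"]


class ConfigError(ValueError):
    """Invalid or incomplete experiment configuration."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


#: Volume-ratio evaluation conditions for the mixture test protocol.
MIXTURE_CONDITIONS: dict[str, dict[str, float]] = {
    "binary_5": {"thiram": 0.05, "TBZ": 0.95},
    "binary_10": {"thiram": 0.10, "TBZ": 0.90},
    "ternary_5": {"thiram": 0.05, "TBZ": 0.475, "CBZ": 0.475},
    "ternary_10": {"thiram": 0.10, "TBZ": 0.45, "CBZ": 0.45},
}


@dataclass
class ExperimentConfig:
    grid: Grid = field(default_factory=Grid)
    libraries: dict[str, PeakLibrary] = field(default_factory=default_libraries)
    concentrations: tuple[float, ...] = (1e-4, 5e-5, 1e-5, 5e-6, 1e-6, 5e-7)
    n_per_concentration: int = 40
    noise: NoiseModel = field(default_factory=NoiseModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    n_pos: int = 1300  # positives drawn for the classification dataset
    n_per_neg: int = 325  # per negative source
    split: SplitConfig = field(default_factory=SplitConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    top_k: int = 450
    cnn: CNNConfig = field(default_factory=CNNConfig)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    tune: bool = False
    tune_budget: int = 10
    tune_folds: int = 5
    search_space: dict = field(default_factory=lambda: {
        "batch_size": [32, 64, 128],
        "lr": (1e-4, 1e-1),
        "dropout": [0.3, 0.5, 0.7],
        "weight_decay": (1e-6, 1e-2),
        "momentum": [0.0, 0.5, 0.9],
    })
    mixture_conditions: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(MIXTURE_CONDITIONS))
    mixture_concentration: float = 1e-5
    test_n_pos: int = 20
    test_n_per_neg: int = 5
    negatives_as_printed: bool = False  # True: thiram/TBZ/CBZ/substrate as negative sources
    normalization_baselines: str = "vector"  # SVM/KNN input normalization
    master_seed: int = 0

    # -- construction ----------------------------------------------------

    @staticmethod
    def default(master_seed: int = 0) -> "ExperimentConfig":
        return ExperimentConfig(master_seed=master_seed)

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return ExperimentConfig.from_dict(data)

    @staticmethod
    def from_dict(data: dict) -> "ExperimentConfig":
        if "libraries" not in data:
            raise ConfigError("config is missing the required 'libraries' section")
        cfg = ExperimentConfig()
        libs = {}
        for name, spec in data["libraries"].items():
            peaks = tuple(Peak(*map(float, p)) for p in spec["peaks"])
            resp = (FourPLParams(**spec["response"]) if "response" in spec
                    else PeakLibrary.__dataclass_fields__["response"].default)
            libs[name] = PeakLibrary(name, peaks, response=resp,
                                     affinity=float(spec.get("affinity", 1.0)))
        kwargs: dict = {"libraries": libs}
        if "grid" in data:
            kwargs["grid"] = Grid(**data["grid"])
        if "noise" in data:
            kwargs["noise"] = NoiseModel(**data["noise"])
        if "preprocess" in data:
            kwargs["preprocess"] = PreprocessConfig(**data["preprocess"])
        if "augment" in data:
            kwargs["augment"] = AugmentConfig(**{
                k: tuple(v) if k == "probs" else v for k, v in data["augment"].items()})
        if "split" in data:
            kwargs["split"] = SplitConfig(**data["split"])
        if "forest" in data:
            kwargs["forest"] = ForestConfig(**data["forest"])
        if "cnn" in data:
            kwargs["cnn"] = CNNConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in data["cnn"].items()})
        if "hyperparams" in data:
            kwargs["hyperparams"] = Hyperparams(**data["hyperparams"])
        for key in ("concentrations", "n_per_concentration", "n_pos", "n_per_neg",
                    "top_k", "tune", "tune_budget", "tune_folds", "mixture_conditions",
                    "mixture_concentration", "test_n_pos", "test_n_per_neg",
                    "negatives_as_printed", "normalization_baselines", "master_seed"):
            if key in data:
                kwargs[key] = tuple(data[key]) if key == "concentrations" else data[key]
        return ExperimentConfig(**{**asdict_defaults(cfg), **kwargs})

    # -- provenance ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "grid": {"lo": self.grid.lo, "hi": self.grid.hi, "n": self.grid.n},
            "libraries": {
                name: {
                    "peaks": [[p.center, p.fwhm, p.rel_amp] for p in lib.peaks],
                    "affinity": lib.affinity,
                    "response": asdict(lib.response),
                }
                for name, lib in self.libraries.items()
            },
            "concentrations": list(self.concentrations),
            "n_per_concentration": self.n_per_concentration,
            "noise": asdict(self.noise),
            "preprocess": asdict(self.preprocess),
            "augment": {**asdict(self.augment), "probs": list(self.augment.probs)},
            "n_pos": self.n_pos,
            "n_per_neg": self.n_per_neg,
            "split": asdict(self.split),
            "forest": asdict(self.forest),
            "top_k": self.top_k,
            "cnn": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in asdict(self.cnn).items()},
            "hyperparams": asdict(self.hyperparams),
            "tune": self.tune,
            "tune_budget": self.tune_budget,
            "tune_folds": self.tune_folds,
            "mixture_conditions": self.mixture_conditions,
            "mixture_concentration": self.mixture_concentration,
            "test_n_pos": self.test_n_pos,
            "test_n_per_neg": self.test_n_per_neg,
            "negatives_as_printed": self.negatives_as_printed,
            "normalization_baselines": self.normalization_baselines,
            "master_seed": self.master_seed,
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]

    def negative_names(self) -> list[str]:
        """Negative-source analytes for the mixture test protocol."""
        if self.negatives_as_printed:
            return ["thiram", "TBZ", "CBZ", "substrate"]
        return ["TBZ", "CBZ", "phosmet", "substrate"]


def asdict_defaults(cfg: ExperimentConfig) -> dict:
    """Field→value mapping of a config without deep-copying nested dataclasses."""
    return {name: getattr(cfg, name) for name in cfg.__dataclass_fields__}
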