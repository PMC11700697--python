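"""Run configuration: plain-text YAML with validated, documented defaults.

Unknown keys are rejected so silent typos cannot change an analysis. The
defaults are the study's analysis constants: 1-4 MHz APSD band, 0.9
correlation threshold, 3-cluster waveband cut, GA population 64 / 50
generations / 100 runs, 10-fold cross-validation, K = 3, and the 10^-6 to
10^9 SVM hyperparameter grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .synth import ClassParams, DEFAULT_CANCER, DEFAULT_NORMAL


@dataclass
class GeneratorBlock:
    n_normal: int = 50
    n_cancer: int = 50
    trace_length: int = 4096
    sampling_rate_hz: float = 250e6
    pulse_center_mhz: float = 2.5
    pulse_fractional_bw: float = 0.8
    noise_sd: float = 0.005
    energy_jitter_sigma: float = 0.10
    blackbody_amplitude: float = 0.5
    apply_hydrophone: bool = True
    normal: ClassParams = field(default_factory=lambda: DEFAULT_NORMAL)
    cancer: ClassParams = field(default_factory=lambda: DEFAULT_CANCER)


@dataclass
class ProcessingBlock:
    highpass_cutoff_hz: float = 1e6
    f0_mhz: float = 1.0
    f1_mhz: float = 4.0
    welch_window_fraction: float = 0.125
    welch_overlap: float = 0.5


@dataclass
class UnsupervisedBlock:
    tau: float = 0.9
    k_clusters: int = 3
    linkage: str = "complete"
    walktrap_steps: int = 4
    network_class: str = "cancer"


@dataclass
class GABlock:
    population_size: int = 64
    generations: int = 50
    runs: int = 100
    init_prob: float = 0.15
    mutation_rate: float = 0.005
    cv_folds: int = 5


@dataclass
class ClassificationBlock:
    models: tuple = ("knn", "plsda", "svmda")
    folds: int = 10
    knn_k: int = 3
    svm_grid_points: int = 16
    svm_grid_min_exp: float = -6.0
    svm_grid_max_exp: float = 9.0


@dataclass
class RunConfig:
    seed: int = 11
    generator: GeneratorBlock = field(default_factory=GeneratorBlock)
    processing: ProcessingBlock = field(default_factory=ProcessingBlock)
    unsupervised: UnsupervisedBlock = field(default_factory=UnsupervisedBlock)
    ga: GABlock = field(default_factory=GABlock)
    classification: ClassificationBlock = field(default_factory=ClassificationBlock)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"config block {context!r} must be a mapping")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r} in {context!r}")
    kwargs = {}
    for name, value in data.items():
        ftype = allowed[name].type
        target = {"normal": ClassParams, "cancer": ClassParams}.get(name)
        if target is None:
            for block in (
                GeneratorBlock,
                ProcessingBlock,
                UnsupervisedBlock,
                GABlock,
                ClassificationBlock,
            ):
                if ftype == block.__name__ or ftype is block:
                    target = block
        if target is not None and is_dataclass(target):
            kwargs[name] = _build(target, value, f"{context}.{name}")
        elif name == "models" and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys.

    Missing keys take their documented defaults; ``overrides`` (e.g. a CLI
    ``--seed``) are applied last.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            data = loaded
    cfg = _build(RunConfig, data, "run")
    if overrides:
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config override {key!r}")
            setattr(cfg, key, value)
    return cfg
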