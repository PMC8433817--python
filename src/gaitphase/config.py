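"""Run configuration: YAML loading, profiles and run metadata.

Every pipeline run resolves its full parameter set (all defaults filled
in) and writes it as a run-metadata YAML file *before* computing, so any
output can be regenerated from that file and the seed alone.  Two
profiles exist: ``paper_fidelity`` (full-size models, 100 epochs, raw
imbalanced window stream) and ``desk_scale`` (reduced units, 10 epochs,
balanced windows) for single-CPU work.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gaitphase.event_caller import CallerConfig
from gaitphase.gait_labeler import LabelerConfig
from gaitphase.gait_synth import SynthConfig, StepTemplate
from gaitphase.phase_model import ModelSpec, TrainConfig
from gaitphase.preprocess import PreprocessConfig

PROFILES = ("paper_fidelity", "desk_scale")


@dataclass(frozen=True)
class BalanceConfig:
    """Window-balancing choices (see windowing.balance_windows)."""

    strategy: str = "target_dilation"
    ratio: float = 2.0
    dilation_radius: int = 2
    hard_negative_radius: int | None = 125
    hard_fraction: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """All stage configurations plus the global seed and profile."""

    seed: int = 0
    profile: str = "desk_scale"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    labeler: LabelerConfig = field(default_factory=LabelerConfig)
    model: ModelSpec = field(default_factory=ModelSpec.desk_scale)
    training: TrainConfig = field(default_factory=TrainConfig.desk_scale)
    caller: CallerConfig = field(default_factory=CallerConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")

    @classmethod
    def for_profile(cls, profile: str, seed: int = 0) -> "RunConfig":
        if profile == "paper_fidelity":
            return cls(
                seed=seed,
                profile=profile,
                model=ModelSpec(),
                training=TrainConfig(seed=seed),
                balance=BalanceConfig(strategy="none"),
            )
        return cls(seed=seed, profile=profile,
                   training=TrainConfig.desk_scale(seed=seed))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise KeyError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


def load_run_config(path=None, profile: str = "desk_scale", seed: int | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    File keys mirror the dataclass structure (``preprocess:``,
    ``labeler:``, ``model:``, ``training:``, ``caller:``, ``synth:``,
    ``balance:``, ``seed:``, ``profile:``).  ``seed`` and ``overrides``
    given here win over the file.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for section, values in overrides.items():
            data.setdefault(section, {}).update(values)
    profile = data.pop("profile", profile)
    base = RunConfig.for_profile(profile, seed=data.pop("seed", seed or 0))
    if seed is not None:
        base = dataclasses.replace(base, seed=seed)
    kwargs = {}
    section_types = {
        "preprocess": PreprocessConfig,
        "labeler": LabelerConfig,
        "model": ModelSpec,
        "training": TrainConfig,
        "caller": CallerConfig,
        "synth": SynthConfig,
        "balance": BalanceConfig,
    }
    for name, cls in section_types.items():
        if name in data:
            section = dict(data[name])
            if name == "model" and "units" in section:
                section["units"] = tuple(section["units"])
            if name == "synth" and "step_templates" in section:
                section["step_templates"] = {
                    k: StepTemplate(**v) if isinstance(v, dict) else v
                    for k, v in section["step_templates"].items()
                }
            base_section = getattr(base, name)
            kwargs[name] = dataclasses.replace(base_section, **section) \
                if dataclasses.is_dataclass(base_section) else _build(cls, section)
    if seed is not None:
        for sec in ("training", "synth"):
            if sec not in kwargs:
                kwargs[sec] = dataclasses.replace(getattr(base, sec), seed=seed)
            elif "seed" not in (data.get(sec) or {}):
                kwargs[sec] = dataclasses.replace(kwargs[sec], seed=seed)
    return dataclasses.replace(base, **kwargs)
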