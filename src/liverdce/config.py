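"""Pipeline configuration: schema, validation, YAML loading.

A single config drives the whole comparison study.  Unknown keys are
rejected so typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .aif import InjectionProtocol
from .kinetics import FitOptions

__all__ = [
    "AcquisitionBlock",
    "RelaxationBlock",
    "MetricsBlock",
    "StatsBlock",
    "SimulateBlock",
    "InputsBlock",
    "PipelineConfig",
    "load_config",
]


@dataclass
class AcquisitionBlock:
    """Sequence parameters of both protocols (study defaults baked in)."""

    prebolus_tr: float = 0.0023
    prebolus_te: float = 0.00091
    prebolus_flip_deg: float = 12.0
    prebolus_recovery_time: float = 0.120
    mainbolus_tr: float = 0.00296
    mainbolus_te: float = 0.00095
    mainbolus_flip_deg: float = 12.0


@dataclass
class RelaxationBlock:
    t10_blood: float = 1.2     # pre-contrast blood T1 [s]
    t10_liver: float = 0.58    # fallback liver T1 [s] when not given per subject
    r1: float = 6.3            # contrast relaxivity [L/(mmol*s)]


@dataclass
class MetricsBlock:
    n_baseline_pre: int = 25   # pre-bolus baseline samples (5 s at 0.2 s)
    n_baseline_main: int = 3   # the 3 pre-contrast volumes
    k_sd: float = 3.0          # arrival threshold in baseline SDs
    conc_max: float = 50.0     # inversion bracket upper bound [mmol/L]


@dataclass
class StatsBlock:
    ba_mode: str = "percent"   # Bland-Altman difference mode


@dataclass
class SimulateBlock:
    n_subjects: int = 20
    master_seed: int = 123
    retest: bool = False
    noise_sd: float | None = None           # override generator default
    inflow_amplitude: float | None = None   # override generator default
    snap_delays: float | None = None


@dataclass
class InputsBlock:
    """File-based cohort: a manifest CSV naming each subject's series."""

    manifest: str = ""


@dataclass
class FitBlock:
    tau_a_max: float = 10.0
    tau_p_max: float = 15.0
    delay_step: float = 0.5
    frame_average: float | None = 3.2
    reconstruction_mode: str = "fractional"

    def to_fit_options(self) -> FitOptions:
        return FitOptions(
            tau_a_max=self.tau_a_max,
            tau_p_max=self.tau_p_max,
            delay_step=self.delay_step,
            frame_average=self.frame_average,
        )


@dataclass
class ProtocolBlock:
    pre_volume_ml: float = 1.3
    pre_rate_ml_s: float = 4.1
    main_dose_mmol_per_kg: float = 0.05
    weight_kg: float = 70.0
    agent_molarity_mmol_ml: float = 0.5
    main_rate_ml_s: float = 5.0

    def to_protocol(self) -> InjectionProtocol:
        return InjectionProtocol(
            pre_volume_ml=self.pre_volume_ml,
            pre_rate_ml_s=self.pre_rate_ml_s,
            main_dose_mmol_per_kg=self.main_dose_mmol_per_kg,
            weight_kg=self.weight_kg,
            agent_molarity_mmol_ml=self.agent_molarity_mmol_ml,
            main_rate_ml_s=self.main_rate_ml_s,
        )


@dataclass
class PipelineConfig:
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    inputs: InputsBlock | None = None
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    acquisition: AcquisitionBlock = field(default_factory=AcquisitionBlock)
    relaxation: RelaxationBlock = field(default_factory=RelaxationBlock)
    metrics: MetricsBlock = field(default_factory=MetricsBlock)
    fit: FitBlock = field(default_factory=FitBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' or an 'inputs' block")


def _build(cls, data, path="config"):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        return None
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = _SUBBLOCKS.get((cls, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SUBBLOCKS = {
    (PipelineConfig, "simulate"): SimulateBlock,
    (PipelineConfig, "inputs"): InputsBlock,
    (PipelineConfig, "protocol"): ProtocolBlock,
    (PipelineConfig, "acquisition"): AcquisitionBlock,
    (PipelineConfig, "relaxation"): RelaxationBlock,
    (PipelineConfig, "metrics"): MetricsBlock,
    (PipelineConfig, "fit"): FitBlock,
    (PipelineConfig, "stats"): StatsBlock,
}


def config_from_dict(data: dict) -> PipelineConfig:
    cfg = _build(PipelineConfig, dict(data))
    # an explicit inputs block disables simulation unless asked for
    if "inputs" in data and "simulate" not in data:
        cfg.simulate = None
    return cfg


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML (or JSON, a YAML subset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return config_from_dict(data)
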