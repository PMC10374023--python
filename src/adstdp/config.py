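"""Configuration objects for the spike-pattern-detection simulator.

All model parameters live in small frozen dataclasses so that a run is fully
described by one :class:`ExperimentConfig`.  The four experimental setups
(all-afferents vs. half-afferents encoding the pattern, with and without
extra noise/jitter) are available as presets via :func:`experiment_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the stochastic input spike-train generator.

    The generator produces, per afferent, an inhomogeneous Poisson spike
    train whose instantaneous rate wanders between ``rate_min`` and
    ``rate_max`` with bounded slope, enforces at least one spike per
    ``min_activity_window``, embeds a repeating ``section_len``-long spike
    pattern in a fraction ``appearance_rate`` of the sections, and finally
    adds homogeneous Poisson noise and Gaussian jitter on pattern spikes.
    """

    n_aff: int = 256
    n_active: int = 256
    duration: float = 225.0
    section_len: float = 0.050
    appearance_rate: float = 0.25
    rate_min: float = 0.0
    rate_max: float = 90.0
    max_ramp_time: float = 0.050
    min_activity_window: float = 0.050
    noise_rate: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_aff <= 0:
            raise ConfigurationError("n_aff must be positive")
        if not (0 < self.n_active <= self.n_aff):
            raise ConfigurationError("need 0 < n_active <= n_aff")
        if self.duration < 0:
            raise ConfigurationError("duration must be non-negative")
        if self.section_len <= 0:
            raise ConfigurationError("section_len must be positive")
        n_sections = self.duration / self.section_len
        if abs(n_sections - round(n_sections)) > 1e-9 * max(1.0, n_sections):
            raise ConfigurationError(
                "duration must be an integer multiple of section_len"
            )
        if not (0.0 <= self.appearance_rate <= 1.0):
            raise ConfigurationError("appearance_rate must lie in [0, 1]")
        if self.rate_min > self.rate_max:
            raise ConfigurationError("rate_min must not exceed rate_max")
        if self.rate_min < 0:
            raise ConfigurationError("rate_min must be non-negative")
        if self.max_ramp_time <= 0:
            raise ConfigurationError("max_ramp_time must be positive")
        if self.min_activity_window <= 0:
            raise ConfigurationError("min_activity_window must be positive")
        if self.noise_rate < 0:
            raise ConfigurationError("noise_rate must be non-negative")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be non-negative")

    @property
    def n_sections(self) -> int:
        return int(round(self.duration / self.section_len))

    @property
    def max_slope(self) -> float:
        """Largest admissible |dr/dt| in Hz/s."""
        return (self.rate_max - self.rate_min) / self.max_ramp_time


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire soma, in normalised units.

    The membrane is normalised so that the spiking threshold sits at 1 and
    the baseline resting potential at 0 (depolarisation increases v).  The
    ``v_rest`` offset implements the per-setup resting-potential shift used
    when only half of the afferents carry the pattern.
    """

    tau_m: float = 0.005      # s, fast-spiking soma
    v_rest: float = 0.0
    v_thresh: float = 1.0
    v_reset: float = -1.0     # hyperpolarising after-spike reset
    refractory: float = 0.002  # s, matches the ~2 ms spike width of the soma

    def validate(self) -> None:
        if self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive")
        if self.v_thresh <= self.v_rest:
            raise ConfigurationError("v_thresh must exceed v_rest")
        if self.refractory < 0:
            raise ConfigurationError("refractory must be non-negative")


@dataclass(frozen=True)
class SynapseParams:
    """Exponential-kernel synapse with a linear 4-bit efficacy -> amplitude map.

    A presynaptic event at a synapse with integer efficacy w injects a
    current step of ``w * unit_amp`` that then decays with time constant
    ``tau_s`` -- the behavioural analogue of a binary-weighted DAC feeding a
    log-domain integrator.
    """

    tau_s: float = 0.0025     # s
    unit_amp: float = 1.3     # drive units per efficacy step (calibrated)
    levels: int = 16

    def validate(self) -> None:
        if self.tau_s <= 0:
            raise ConfigurationError("tau_s must be positive")
        if self.unit_amp <= 0:
            raise ConfigurationError("unit_amp must be positive")
        if self.levels < 2:
            raise ConfigurationError("levels must be at least 2")

    @property
    def w_max(self) -> int:
        return self.levels - 1


SCHEDULE_SHAPES = ("linear", "exponential", "stepwise")


@dataclass(frozen=True)
class PlasticityParams:
    """Adaptive-STDP parameters.

    Rectangular coincidence windows: a pre spike at most ``t_pre`` before a
    post spike potentiates (+1), a pre spike at most ``tpost(t)`` after a
    post spike depresses (-1).  ``t_pre`` is fixed; the depression window
    grows from ``t_post_init`` to ``t_post_final`` over ``t_adapt`` seconds.
    """

    t_pre: float = 0.005
    t_post_init: float = 0.0055
    t_post_final: float = 0.026
    t_adapt: float = 100.0
    schedule_shape: str = "exponential"

    def validate(self) -> None:
        if self.t_pre <= 0:
            raise ConfigurationError("t_pre must be positive")
        if self.t_post_init < 0:
            raise ConfigurationError("t_post_init must be non-negative")
        if self.t_post_final < self.t_post_init:
            raise ConfigurationError("t_post_final must be >= t_post_init")
        if self.t_adapt <= 0:
            raise ConfigurationError("t_adapt must be positive")
        if self.schedule_shape not in SCHEDULE_SHAPES:
            raise ConfigurationError(
                f"schedule_shape must be one of {SCHEDULE_SHAPES}"
            )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one closed-loop learning experiment."""

    setup_id: int = 1
    appearance_rate: float = 0.25
    n_runs: int = 50
    base_seed: int = 0
    dt: float = 1e-4
    initial_efficacy: int = 5
    weight_snapshot_every: float = 5.0
    freeze_learning: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)

    def validate(self) -> None:
        if self.setup_id not in (1, 2, 3, 4):
            raise ConfigurationError("setup_id must be 1..4")
        if not (0 <= self.initial_efficacy <= self.synapse.w_max):
            raise ConfigurationError("initial_efficacy out of range")
        if self.dt <= 0 or self.dt > self.neuron.tau_m / 10:
            raise ConfigurationError("dt must satisfy 0 < dt <= tau_m/10")
        if self.weight_snapshot_every <= 0:
            raise ConfigurationError("weight_snapshot_every must be positive")
        self.generator.validate()
        self.neuron.validate()
        self.synapse.validate()
        self.plasticity.validate()


# Per-setup presets.  n_active and the noise/jitter flags follow the
# experimental design; initial efficacy per setup is 5/4/6/4; the resting
# potential is raised toward threshold when only 128 afferents carry the
# pattern; the final depression window is widest in the noise-free setups
# and narrows as the input gets noisier.
_REST_OFFSET_HALF = 0.1875   # fraction of (v_thresh - v_rest) for setups 2/4

_SETUPS: dict[int, dict[str, Any]] = {
    1: dict(n_active=256, noise_rate=0.0, jitter_sd=0.0,
            initial_efficacy=5, rest_offset=0.0, t_post_final=0.026),
    2: dict(n_active=128, noise_rate=0.0, jitter_sd=0.0,
            initial_efficacy=4, rest_offset=_REST_OFFSET_HALF,
            t_post_final=0.026),
    3: dict(n_active=256, noise_rate=10.0, jitter_sd=0.001,
            initial_efficacy=6, rest_offset=0.0, t_post_final=0.017),
    4: dict(n_active=128, noise_rate=10.0, jitter_sd=0.001,
            initial_efficacy=4, rest_offset=_REST_OFFSET_HALF,
            t_post_final=0.015),
}


def experiment_config(
    setup_id: int,
    appearance_rate: float = 0.25,
    *,
    n_runs: int = 50,
    base_seed: int = 0,
    **overrides: Any,
) -> ExperimentConfig:
    """Build the preset :class:`ExperimentConfig` for one of the four setups.

    ``overrides`` may address nested fields with dotted keys, e.g.
    ``experiment_config(1, 0.25, **{"plasticity.t_pre": 0.02})``.
    """
    if setup_id not in _SETUPS:
        raise ConfigurationError("setup_id must be 1..4")
    preset = _SETUPS[setup_id]
    neuron = NeuronParams(v_rest=preset["rest_offset"])
    cfg = ExperimentConfig(
        setup_id=setup_id,
        appearance_rate=appearance_rate,
        n_runs=n_runs,
        base_seed=base_seed,
        initial_efficacy=preset["initial_efficacy"],
        generator=GeneratorConfig(
            n_active=preset["n_active"],
            appearance_rate=appearance_rate,
            noise_rate=preset["noise_rate"],
            jitter_sd=preset["jitter_sd"],
        ),
        neuron=neuron,
        plasticity=PlasticityParams(t_post_final=preset["t_post_final"]),
    )
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    cfg.validate()
    return cfg


def _replace_nested(obj: Any, path: list[str], value: Any) -> Any:
    head = path[0]
    if not hasattr(obj, head):
        raise ConfigurationError(f"unknown config field {'.'.join(path)!r}")
    if len(path) == 1:
        current = getattr(obj, head)
        if current is not None and not isinstance(value, type(current)):
            value = type(current)(value)
        return dataclasses.replace(obj, **{head: value})
    child = _replace_nested(getattr(obj, head), path[1:], value)
    return dataclasses.replace(obj, **{head: child})


def apply_overrides(cfg: ExperimentConfig, overrides: dict[str, Any]) -> ExperimentConfig:
    """Apply dotted-key overrides such as ``{"neuron.tau_m": 0.02}``."""
    for key, value in overrides.items():
        cfg = _replace_nested(cfg, key.split("."), value)
    return cfg


def to_yaml(cfg: ExperimentConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=False)


def from_yaml(text: str) -> ExperimentConfig:
    raw = yaml.safe_load(text) or {}
    nested = {
        "generator": GeneratorConfig,
        "neuron": NeuronParams,
        "synapse": SynapseParams,
        "plasticity": PlasticityParams,
    }
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**(value or {}))
        else:
            kwargs[key] = value
    cfg = ExperimentConfig(**kwargs)
    cfg.validate()
    return cfg
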