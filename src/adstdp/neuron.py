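"""Behavioural soma + synapse model.

The soma is a leaky integrate-and-fire unit in normalised polarity
(depolarisation increases v, threshold at v_thresh).  Each of the 256
synapses injects, per presynaptic event, an exponentially decaying current
whose amplitude is linear in its 4-bit integer efficacy — the behavioural
equivalent of a binary-weighted DAC feeding a log-domain integrator.
Because every synapse shares one decay constant, the whole population is
carried as a single summed current accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import GeneratorConfig, NeuronParams, SynapseParams

__all__ = [
    "NeuronState",
    "new_weight_vector",
    "check_weights",
    "psc_increment",
    "decay_step",
    "lif_step",
    "initial_rate_check",
]


def new_weight_vector(n_aff: int, value: int, levels: int = 16) -> np.ndarray:
    """Integer efficacy vector, all synapses initialised to ``value``."""
    if not (0 <= value < levels):
        raise ValueError(f"efficacy {value} outside [0, {levels})")
    return np.full(n_aff, value, dtype=np.int64)


def check_weights(w: np.ndarray, levels: int = 16) -> None:
    if w.min(initial=0) < 0 or w.max(initial=0) >= levels:
        raise ValueError("weight vector outside its saturation bounds")


@dataclass
class NeuronState:
    """Mutable state of the soma plus the shared synaptic-current accumulator."""

    v: float
    syn_current: float = 0.0
    last_spike_time: Optional[float] = None


def psc_increment(j: int, w: np.ndarray, sp: SynapseParams,
                  state: NeuronState) -> NeuronState:
    """Deliver a presynaptic event at synapse j: current jumps by w_j * unit_amp.

    The subsequent exponential decay (time constant tau_s) is applied by
    :func:`decay_step`, so the total charge injected per event is
    ``w_j * unit_amp * tau_s``.
    """
    state.syn_current += w[j] * sp.unit_amp
    return state


def decay_step(state: NeuronState, dt: float, sp: SynapseParams) -> NeuronState:
    state.syn_current *= np.exp(-dt / sp.tau_s)
    return state


def lif_step(state: NeuronState, i_total: float, dt: float,
             np_: NeuronParams, t_next: Optional[float] = None):
    """One exponential-Euler membrane update; returns ``(state, spiked)``.

    The membrane relaxes toward ``v_rest + tau_m * i_total``; crossing
    ``v_thresh`` outside the refractory period emits a spike and resets v.
    During the refractory period v is clamped at ``v_reset``.
    """
    if not np.isfinite(i_total):
        raise FloatingPointError("non-finite input current")
    if t_next is None:
        t_next = (state.last_spike_time or 0.0) + dt
    in_refractory = (state.last_spike_time is not None
                     and t_next - state.last_spike_time < np_.refractory)
    if in_refractory:
        state.v = np_.v_reset
        return state, False
    decay = np.exp(-dt / np_.tau_m)
    state.v = (np_.v_rest + (state.v - np_.v_rest) * decay
               + i_total * np_.tau_m * (1.0 - decay))
    if state.v >= np_.v_thresh:
        state.v = np_.v_reset
        state.last_spike_time = t_next
        return state, True
    return state, False


def initial_rate_check(gen_cfg: GeneratorConfig, np_: NeuronParams,
                       sp: SynapseParams, w0: np.ndarray,
                       duration: float = 5.0, dt: float = 1e-4,
                       seed: int = 0) -> float:
    """Open-loop firing rate (Hz) over the first ``duration`` seconds.

    Runs the neuron with plasticity disabled on a freshly generated input;
    used to calibrate ``unit_amp`` so that each setup's initial efficacy
    drives the soma in the 40–200 Hz range at the start of learning.
    """
    from . import simulator  # local import to avoid a cycle

    check_weights(w0, sp.levels)
    import dataclasses
    cfg = dataclasses.replace(gen_cfg, duration=float(
        np.ceil(duration / gen_cfg.section_len) * gen_cfg.section_len),
        seed=seed)
    train, _ = _generate(cfg)
    post = simulator.simulate_train(train, w0.copy(), np_, sp,
                                    plasticity=None, dt=dt)
    in_window = post[post < duration]
    return in_window.size / duration


def _generate(cfg: GeneratorConfig):
    from .spikegen import generate
    return generate(cfg)
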