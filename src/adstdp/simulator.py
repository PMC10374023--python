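"""Closed-loop simulation: generator -> synapses -> soma -> plasticity.

One :func:`run` generates an input train for the configured setup, plays
it through the LIF neuron at a fixed time step with the adaptive-STDP rule
updating the 4-bit efficacies online, and scores the outcome over the
final third of the run.  :func:`run_batch` repeats this over independent
seeds and aggregates the success rate, mirroring the 50-runs-per-setup
protocol of the experiments.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import evaluate, spikegen
from ._kernels import run_closed_loop
from .config import (ExperimentConfig, NeuronParams, PlasticityParams,
                     SynapseParams)
from .plasticity import schedule_code

__all__ = ["RunResult", "BatchResult", "run", "run_batch", "simulate_train"]

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    post_spike_times: np.ndarray
    weight_snapshots: List[Tuple[float, np.ndarray]]
    final_weights: np.ndarray
    pattern_spec: spikegen.PatternSpec
    metrics: evaluate.Metrics
    run_class: evaluate.RunClass
    config: ExperimentConfig
    run_index: int
    seed: int
    delivered_events: int
    n_input_events: int


@dataclass
class BatchResult:
    table: pd.DataFrame
    success_rate: Optional[float]  # None when n_runs == 0


def run_seed(cfg: ExperimentConfig, run_index: int) -> int:
    """Per-run seed: base_seed XOR run_index (kept below 2^31)."""
    return (cfg.base_seed ^ run_index) & 0x7FFFFFFF


def simulate_train(train: spikegen.SpikeTrain, w: np.ndarray,
                   np_: NeuronParams, sp: SynapseParams,
                   plasticity: Optional[PlasticityParams],
                   dt: float = 1e-4,
                   snapshot_every: float = 0.0):
    """Run the time-stepped kernel on one input train.

    ``plasticity=None`` freezes learning (weights stay fixed).  Returns the
    postsynaptic spike times; with ``snapshot_every > 0`` returns
    ``(post_times, snapshots, delivered)`` instead.
    """
    train = train.sorted()
    n_steps = int(round(train.duration / dt))
    w = np.ascontiguousarray(w, dtype=np.int64)

    if plasticity is None:
        pp = PlasticityParams()
        plast_on = False
    else:
        pp = plasticity
        plast_on = True

    snap_steps = int(round(snapshot_every / dt)) if snapshot_every > 0 else 0
    n_snaps_max = (n_steps // snap_steps + 2) if snap_steps > 0 else 1
    snapshots = np.zeros((n_snaps_max, w.shape[0]), dtype=np.int64)
    post_out = np.empty(n_steps + 1, dtype=np.float64)

    n_post, delivered, n_snaps = run_closed_loop(
        train.times, train.ids, w,
        n_steps, dt,
        np_.tau_m, np_.v_rest, np_.v_thresh, np_.v_reset, np_.refractory,
        sp.tau_s, sp.unit_amp, sp.w_max,
        pp.t_pre, pp.t_post_init, pp.t_post_final, pp.t_adapt,
        schedule_code(pp.schedule_shape),
        plast_on,
        snap_steps, snapshots,
        post_out,
    )
    post = post_out[:n_post].copy()
    if snapshot_every > 0:
        snaps = [(i * snap_steps * dt, snapshots[i].copy())
                 for i in range(n_snaps)]
        return post, snaps, delivered, w
    return post


def run(cfg: ExperimentConfig, run_index: int = 0) -> RunResult:
    """One complete learning run; bitwise reproducible given (cfg, run_index)."""
    cfg.validate()
    seed = run_seed(cfg, run_index)
    gen_cfg = dataclasses.replace(cfg.generator, seed=seed)
    train, spec = spikegen.generate(gen_cfg)

    w0 = np.full(gen_cfg.n_aff, cfg.initial_efficacy, dtype=np.int64)
    plast = None if cfg.freeze_learning else cfg.plasticity
    post, snaps, delivered, w_final = simulate_train(
        train, w0, cfg.neuron, cfg.synapse, plast, dt=cfg.dt,
        snapshot_every=cfg.weight_snapshot_every,
    )
    snaps.append((gen_cfg.duration, w_final.copy()))

    _warn_if_unstable(post, cfg.neuron.refractory)

    window = evaluate.default_window(gen_cfg.duration)
    metrics = evaluate.score(post, spec, window)
    run_class = evaluate.classify_run(metrics)
    return RunResult(
        post_spike_times=post,
        weight_snapshots=snaps,
        final_weights=w_final,
        pattern_spec=spec,
        metrics=metrics,
        run_class=run_class,
        config=cfg,
        run_index=run_index,
        seed=seed,
        delivered_events=delivered,
        n_input_events=train.n_events,
    )


def _warn_if_unstable(post: np.ndarray, refractory: float) -> None:
    """Log when the neuron saturates at its refractory-limited rate >1 s."""
    if refractory <= 0 or post.size == 0:
        return
    limit = 0.95 / refractory
    edges = np.arange(0.0, post[-1] + 1.0, 1.0)
    counts, _ = np.histogram(post, bins=edges)
    if (counts >= limit).any():
        log.warning("neuron firing near the refractory-limited rate for >1 s")


def run_batch(cfg: ExperimentConfig) -> BatchResult:
    """Repeat :func:`run` for run_index = 0..n_runs-1 and tabulate."""
    rows = []
    for k in range(cfg.n_runs):
        res = run(cfg, k)
        hist = evaluate.weight_histogram(res.final_weights, cfg.synapse.levels)
        n = res.final_weights.size
        rows.append(dict(
            run_index=k,
            seed=res.seed,
            hit_rate=res.metrics.hit_rate,
            false_alarms=res.metrics.false_alarms,
            double_spike_patterns=res.metrics.double_spike_patterns,
            run_class=res.run_class.category,
            success=res.metrics.success,
            failed=res.metrics.failed,
            frac_saturated=(hist[0] + hist[-1]) / n,
            mean_weight=res.final_weights.mean(),
        ))
    table = pd.DataFrame(
        rows, columns=["run_index", "seed", "hit_rate", "false_alarms",
                       "double_spike_patterns", "run_class", "success",
                       "failed", "frac_saturated", "mean_weight"])
    success_rate = float(table["success"].mean()) if cfg.n_runs > 0 else None
    return BatchResult(table=table, success_rate=success_rate)
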