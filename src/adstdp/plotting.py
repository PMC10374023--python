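"""Diagnostic figures: raster, efficacy histogram, latency trajectory."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import evaluate
from .simulator import RunResult
from .spikegen import PatternSpec, SpikeTrain

__all__ = ["plot_raster", "plot_run_diagnostics"]


def plot_raster(train: SpikeTrain, spec: Optional[PatternSpec] = None,
                t0: float = 0.0, t1: float = 1.0, path=None):
    """Raster of a time slice; pattern presentations shaded."""
    fig, ax = plt.subplots(figsize=(8, 4))
    sel = (train.times >= t0) & (train.times < t1)
    ax.plot(train.times[sel], train.ids[sel], "|", ms=2, color="k")
    if spec is not None:
        for s in spec.occurrences:
            if t0 <= s < t1:
                ax.axvspan(s, s + spec.section_len, color="red", alpha=0.15)
    ax.set(xlabel="time (s)", ylabel="afferent", xlim=(t0, t1))
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_run_diagnostics(res: RunResult, path=None):
    """Three panels: postsynaptic rate, final efficacy histogram, latency."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))

    post = res.post_spike_times
    dur = res.config.generator.duration
    edges = np.arange(0.0, dur + 1.0, 1.0)
    counts, _ = np.histogram(post, bins=edges)
    axes[0].plot(edges[:-1], counts, lw=0.8)
    axes[0].set(xlabel="time (s)", ylabel="rate (Hz)", title="postsynaptic rate")

    hist = evaluate.weight_histogram(res.final_weights)
    axes[1].bar(np.arange(hist.size), hist, color="tab:blue")
    axes[1].set(xlabel="efficacy", ylabel="synapses", title="final efficacies")

    lat = evaluate.latency_series(post, res.pattern_spec)
    xs = [i for i, l in lat if l is not None]
    ys = [1e3 * l for _, l in lat if l is not None]
    axes[2].plot(xs, ys, ".", ms=2)
    axes[2].set(xlabel="occurrence", ylabel="latency (ms)",
                title="latency within pattern")

    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
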