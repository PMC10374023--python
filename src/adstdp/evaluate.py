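"""Scoring of pattern-detection runs.

A postsynaptic spike is a *hit* when it falls inside a pattern
presentation, i.e. inside [start, start + 50 ms) for some occurrence, and
a *false alarm* otherwise.  A run succeeds when, over the scoring window
(by default the final third of the run), the hit rate exceeds 98% with
zero false alarms; a run with no postsynaptic spikes in the window at all
is *failed* (the neuron fell silent during learning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .spikegen import PatternSpec

__all__ = [
    "Metrics",
    "RunClass",
    "score",
    "latency_series",
    "weight_histogram",
    "classify_run",
    "default_window",
]

RUN_CLASSES = ("perfect", "high", "hits_with_FA", "low_hit", "failed")


@dataclass(frozen=True)
class Metrics:
    hit_rate: Optional[float]      # None when no occurrence starts in the window
    false_alarms: int
    double_spike_patterns: int
    success: bool
    failed: bool
    scoring_window: Tuple[float, float]
    n_occurrences: int
    n_spikes: int


@dataclass(frozen=True)
class RunClass:
    category: str

    def __post_init__(self) -> None:
        if self.category not in RUN_CLASSES:
            raise ValueError(f"unknown run class {self.category!r}")


def default_window(duration: float) -> Tuple[float, float]:
    """Scoring window = last third of the run (75 s of a 225 s run)."""
    return (2.0 * duration / 3.0, duration)


def score(post_spikes: np.ndarray, spec: PatternSpec,
          window: Tuple[float, float]) -> Metrics:
    """Hit rate / false alarms over ``window``.

    Hit rate is computed over occurrences *starting* within the window; a
    spike inside any occurrence interval (including one straddling the
    window edge) is never a false alarm.  Order of the input spikes is
    irrelevant.
    """
    t0, t1 = window
    post = np.sort(np.asarray(post_spikes, dtype=float))
    in_win = post[(post >= t0) & (post < t1)]

    occ = np.sort(spec.occurrences)
    L = spec.section_len

    def inside(spikes: np.ndarray) -> np.ndarray:
        if occ.size == 0:
            return np.zeros(spikes.size, dtype=bool)
        idx = np.searchsorted(occ, spikes, side="right") - 1
        ok = idx >= 0
        res = np.zeros(spikes.size, dtype=bool)
        res[ok] = spikes[ok] < occ[idx[ok]] + L
        return res

    false_alarms = int((~inside(in_win)).sum())

    occ_in_win = occ[(occ >= t0) & (occ < t1)]
    if occ_in_win.size:
        counts = np.array([
            int(((post >= s) & (post < s + L)).sum()) for s in occ_in_win
        ])
        hit_rate: Optional[float] = float((counts >= 1).mean())
        doubles = int((counts >= 2).sum())
    else:
        hit_rate = None
        doubles = 0

    failed = in_win.size == 0
    success = (not failed and hit_rate is not None
               and hit_rate > 0.98 and false_alarms == 0)
    return Metrics(hit_rate, false_alarms, doubles, success, failed,
                   (t0, t1), int(occ_in_win.size), int(in_win.size))


def latency_series(post_spikes: np.ndarray,
                   spec: PatternSpec) -> List[Tuple[int, Optional[float]]]:
    """Per occurrence: first-spike latency from pattern onset, or None.

    During learning the neuron's first spike migrates toward the start of
    the pattern, so the latency trend over occurrences is a diagnostic of
    learning progress.
    """
    post = np.sort(np.asarray(post_spikes, dtype=float))
    out: List[Tuple[int, Optional[float]]] = []
    for i, s in enumerate(np.sort(spec.occurrences)):
        k = np.searchsorted(post, s, side="left")
        if k < post.size and post[k] < s + spec.section_len:
            out.append((i, float(post[k] - s)))
        else:
            out.append((i, None))
    return out


def weight_histogram(w: np.ndarray, levels: int = 16) -> np.ndarray:
    """Counts per efficacy level 0..levels-1; sums to the number of synapses."""
    w = np.asarray(w)
    if w.min(initial=0) < 0 or w.max(initial=0) >= levels:
        raise ValueError("weights outside [0, levels)")
    return np.bincount(w.astype(np.int64), minlength=levels)


def classify_run(m: Metrics) -> RunClass:
    """Deterministic run category.

    Precedence failed > perfect > high > hits_with_FA > low_hit resolves
    the overlapping printed boundaries of the run-breakdown table: a run
    with any false alarm (and spikes) lands in ``hits_with_FA``; below-98%
    hit rates without false alarms land in ``low_hit``.
    """
    if m.failed:
        return RunClass("failed")
    hr = m.hit_rate if m.hit_rate is not None else 0.0
    if hr == 1.0 and m.false_alarms == 0:
        return RunClass("perfect")
    if hr > 0.98 and m.false_alarms == 0:
        return RunClass("high")
    if m.false_alarms > 0:
        return RunClass("hits_with_FA")
    return RunClass("low_hit")
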