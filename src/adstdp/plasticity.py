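"""The adaptive-STDP rule.

Rectangular coincidence windows with single-bit updates on a saturating
4-bit counter:

    dw_j = +1  if t_j <= t_i and t_i - t_j < t_pre      (potentiation)
    dw_j = -1  if t_j >  t_i and t_j - t_i < tpost(t)   (depression)

where t_j is the presynaptic and t_i the postsynaptic spike time.  Only the
most recent pre/post pair is eligible: a stored event is *armed* until it
participates in one update, and a newer event of the same kind overwrites
it (re-arming).  The potentiation window t_pre is constant; the depression
window tpost grows monotonically from t_post_init to t_post_final over
t_adapt seconds, which slows learning down and prunes the synapses that
fire uncorrelated with the postsynaptic spike.

This module is the pure-Python reference engine; the time-stepped numba
kernel in ``_kernels`` implements identical semantics and is checked
against it (and against :func:`brute_force_oracle`) in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import (SCHEDULE_EXPONENTIAL, SCHEDULE_LINEAR,
                       SCHEDULE_STEPWISE, _EXP_SHARPNESS, _STEPWISE_STEPS)
from .config import PlasticityParams

__all__ = [
    "PlasticityState",
    "tpost_at",
    "on_pre",
    "on_post",
    "brute_force_oracle",
    "schedule_code",
]

_SCHEDULE_CODES = {
    "linear": SCHEDULE_LINEAR,
    "exponential": SCHEDULE_EXPONENTIAL,
    "stepwise": SCHEDULE_STEPWISE,
}


def schedule_code(shape: str) -> int:
    return _SCHEDULE_CODES[shape]


class SequencingError(RuntimeError):
    """Events must be delivered in non-decreasing time order."""


@dataclass
class PlasticityState:
    """Most-recent-event bookkeeping for one neuron's synapses."""

    n_syn: int
    last_pre: np.ndarray = field(init=False)
    pre_armed: np.ndarray = field(init=False)
    post_armed: np.ndarray = field(init=False)
    last_post: Optional[float] = None
    t_last_event: float = -np.inf

    def __post_init__(self) -> None:
        self.last_pre = np.full(self.n_syn, -np.inf)
        self.pre_armed = np.zeros(self.n_syn, dtype=bool)
        self.post_armed = np.zeros(self.n_syn, dtype=bool)


def tpost_at(t: float, pp: PlasticityParams) -> float:
    """Depression window at wall-clock time t of the run.

    Monotone non-decreasing; equals t_post_init at t=0 and t_post_final for
    every t >= t_adapt, with the transition shaped by ``schedule_shape``.
    """
    if t >= pp.t_adapt:
        return pp.t_post_final
    if t <= 0.0:
        return pp.t_post_init
    x = t / pp.t_adapt
    if pp.schedule_shape == "linear":
        frac = x
    elif pp.schedule_shape == "exponential":
        frac = (1.0 - np.exp(-_EXP_SHARPNESS * x)) / (1.0 - np.exp(-_EXP_SHARPNESS))
    else:  # stepwise
        frac = np.floor(x * _STEPWISE_STEPS) / _STEPWISE_STEPS
    return pp.t_post_init + (pp.t_post_final - pp.t_post_init) * frac


def _check_order(ps: PlasticityState, t: float) -> None:
    if t < ps.t_last_event:
        raise SequencingError(
            f"event at t={t} delivered after t={ps.t_last_event}"
        )
    ps.t_last_event = t


def on_pre(j: int, t: float, ps: PlasticityState, w: np.ndarray,
           pp: PlasticityParams, w_max: int = 15):
    """Presynaptic event at synapse j: possible LTD, then store/arm the pre.

    Depression fires when the most recent postsynaptic spike is still armed
    for this synapse and strictly precedes t by less than tpost(t); the
    window is evaluated at the pre-event time (the decision instant).
    """
    _check_order(ps, t)
    if (ps.last_post is not None and ps.post_armed[j]
            and t > ps.last_post and t - ps.last_post < tpost_at(t, pp)):
        if w[j] > 0:
            w[j] -= 1
        ps.post_armed[j] = False
    ps.last_pre[j] = t
    ps.pre_armed[j] = True
    return ps, w


def on_post(t: float, ps: PlasticityState, w: np.ndarray,
            pp: PlasticityParams, w_max: int = 15):
    """Postsynaptic spike: LTP for every armed pre within t_pre, then re-arm.

    A pre spike coincident with the post (t_j == t_i) falls in the
    potentiation branch, so simultaneous events are processed pre-first.
    """
    _check_order(ps, t)
    for j in range(ps.n_syn):
        if ps.pre_armed[j] and t - ps.last_pre[j] < pp.t_pre:
            if w[j] < w_max:
                w[j] += 1
            ps.pre_armed[j] = False
    ps.last_post = t
    ps.post_armed[:] = True
    return ps, w


def brute_force_oracle(pre_events, post_events, pp: PlasticityParams,
                       w0: np.ndarray, w_max: int = 15) -> np.ndarray:
    """Independent O(n^2) replay of the rule for small event sets.

    ``pre_events`` is an iterable of ``(t, j)`` pairs, ``post_events`` of
    times.  For each event the update decision is derived by direct scans
    over the full event lists (no incremental arming state); the resulting
    +-1 updates are then applied chronologically with saturation.  Intended
    for <= 1e3 events as an exact cross-check of the incremental engine.
    """
    pre = sorted((float(t), int(j)) for t, j in pre_events)
    post = sorted(float(t) for t in post_events)
    w = np.array(w0, dtype=np.int64).copy()

    # (time, pre-before-post order flag, synapse, +-1); coincident events are
    # ranked by list position so duplicated timestamps behave like the
    # sequential engine (earlier event stored/consumed first)
    updates: list[tuple[float, int, int, int]] = []

    # LTP: post #i potentiates synapse j iff the most recent pre of j at
    # tj <= ti lies within t_pre and no earlier post already consumed it
    # (i.e. this is the first post after that pre within the window).
    for i, ti in enumerate(post):
        for j in set(jj for _, jj in pre):
            tj = None
            for t, jj in pre:
                if jj == j and t <= ti:
                    tj = t
            if tj is None or ti - tj >= pp.t_pre:
                continue
            consumed = any(tj <= post[k] and post[k] - tj < pp.t_pre
                           for k in range(i))
            if not consumed:
                updates.append((ti, 1, j, +1))

    # LTD: pre #p of synapse j at tj depresses iff the most recent post ti
    # strictly before tj lies within tpost(tj) and no earlier pre of j
    # after ti already consumed that post.
    for p, (tj, j) in enumerate(pre):
        ti = None
        for tp in post:
            if tp < tj:
                ti = tp
        if ti is None or tj - ti >= tpost_at(tj, pp):
            continue
        consumed = any(
            jj == j and ti < t2 and t2 - ti < tpost_at(t2, pp)
            for t2, jj in pre[:p]
        )
        if not consumed:
            updates.append((tj, 0, j, -1))

    # apply chronologically (pre-before-post at ties) with saturation
    for _, _, j, dw in sorted(updates, key=lambda u: (u[0], u[1])):
        w[j] = min(w_max, max(0, w[j] + dw))
    return w
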