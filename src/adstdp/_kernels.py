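"""Numba-compiled inner loops.

Two hot paths live here: construction of the piecewise-linear bounded rate
walk used by the input generator, and the closed-loop time-stepped
simulation of the LIF neuron with adaptive-STDP synapses.  Everything is
plain arrays + scalars so the kernels stay cache-friendly and trivially
testable against the pure-Python reference implementations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# schedule_shape codes shared with plasticity.tpost_at
SCHEDULE_LINEAR = 0
SCHEDULE_EXPONENTIAL = 1
SCHEDULE_STEPWISE = 2
_EXP_SHARPNESS = 3.0
_STEPWISE_STEPS = 10


@njit(cache=True)
def build_rate_breakpoints(r0, durations, slopes, rate_min, rate_max,
                           duration, bp_t, bp_r):
    """Integrate a clipped piecewise-linear rate walk.

    The walk holds a constant slope for each (exponentially distributed)
    segment duration; when the rate hits a bound it sticks there for the
    remainder of the segment.  Writes breakpoints into bp_t/bp_r and
    returns the number of points.
    """
    n = 0
    bp_t[n] = 0.0
    bp_r[n] = r0
    n += 1
    t = 0.0
    r = r0
    for i in range(durations.shape[0]):
        if t >= duration:
            break
        d = durations[i]
        if t + d > duration:
            d = duration - t
        s = slopes[i]
        r_end = r + s * d
        if r_end > rate_max:
            t_hit = t + (rate_max - r) / s
            bp_t[n] = t_hit
            bp_r[n] = rate_max
            n += 1
            r = rate_max
        elif r_end < rate_min:
            t_hit = t + (rate_min - r) / s
            bp_t[n] = t_hit
            bp_r[n] = rate_min
            n += 1
            r = rate_min
        else:
            r = r_end
        t = t + d
        bp_t[n] = t
        bp_r[n] = r
        n += 1
    if bp_t[n - 1] < duration:
        bp_t[n] = duration
        bp_r[n] = r
        n += 1
    return n


@njit(cache=True, inline="always")
def _tpost_at(t, t_post_init, t_post_final, t_adapt, schedule):
    if t >= t_adapt:
        return t_post_final
    if t <= 0.0:
        return t_post_init
    x = t / t_adapt
    if schedule == SCHEDULE_LINEAR:
        frac = x
    elif schedule == SCHEDULE_EXPONENTIAL:
        frac = (1.0 - np.exp(-_EXP_SHARPNESS * x)) / (1.0 - np.exp(-_EXP_SHARPNESS))
    else:  # stepwise
        frac = np.floor(x * _STEPWISE_STEPS) / _STEPWISE_STEPS
    return t_post_init + (t_post_final - t_post_init) * frac


@njit(cache=True)
def run_closed_loop(spike_times, spike_ids, w,
                    n_steps, dt,
                    tau_m, v_rest, v_thresh, v_reset, refractory,
                    tau_s, unit_amp, w_max,
                    t_pre, t_post_init, t_post_final, t_adapt, schedule,
                    plasticity_on,
                    snapshot_every_steps, snapshots,
                    post_times_out):
    """Exponential-Euler closed loop; returns (n_post, delivered, n_snaps).

    Input spikes must be sorted by time.  Within a step, presynaptic events
    in [t, t+dt) are delivered (plasticity LTD check + current step) before
    the membrane update; a threshold crossing at the end of the step emits
    a postsynaptic spike and runs the LTP pass, so a coincident pre/post
    pair counts as potentiation.
    """
    n_syn = w.shape[0]
    n_ev = spike_times.shape[0]

    decay_m = np.exp(-dt / tau_m)
    decay_s = np.exp(-dt / tau_s)
    drive = tau_m * (1.0 - decay_m)

    last_pre = np.full(n_syn, -1.0e30)
    pre_armed = np.zeros(n_syn, dtype=np.bool_)
    post_armed = np.zeros(n_syn, dtype=np.bool_)
    last_post = -1.0e30

    v = v_rest
    i_syn = 0.0
    last_spike = -1.0e30
    n_post = 0
    delivered = 0
    n_snaps = 0
    ei = 0

    for k in range(n_steps):
        t_next = (k + 1) * dt

        if snapshot_every_steps > 0 and k % snapshot_every_steps == 0:
            for j in range(n_syn):
                snapshots[n_snaps, j] = w[j]
            n_snaps += 1

        # i_syn tracks the summed synaptic current at the END of this step;
        # each event's deposit carries its exact within-step decay, so the
        # current state is dt-independent for the exponential kernel
        i_syn *= decay_s
        while ei < n_ev and spike_times[ei] < t_next:
            tj = spike_times[ei]
            j = spike_ids[ei]
            if plasticity_on:
                if post_armed[j] and tj > last_post:
                    tpost = _tpost_at(tj, t_post_init, t_post_final,
                                      t_adapt, schedule)
                    if tj - last_post < tpost:
                        if w[j] > 0:
                            w[j] -= 1
                        post_armed[j] = False
                last_pre[j] = tj
                pre_armed[j] = True
            i_syn += w[j] * unit_amp * np.exp(-(t_next - tj) / tau_s)
            delivered += 1
            ei += 1

        if t_next - last_spike < refractory:
            v = v_reset
        else:
            v = v_rest + (v - v_rest) * decay_m + i_syn * drive
            if v >= v_thresh:
                post_times_out[n_post] = t_next
                n_post += 1
                v = v_reset
                last_spike = t_next
                if plasticity_on:
                    for j in range(n_syn):
                        if pre_armed[j] and t_next - last_pre[j] < t_pre:
                            if w[j] < w_max:
                                w[j] += 1
                            pre_armed[j] = False
                        post_armed[j] = True
                    last_post = t_next

    return n_post, delivered, n_snaps
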