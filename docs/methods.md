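# Model and methods

This note documents the models implemented in `adstdp`, the reasoning
behind every tunable constant, what the synthetic inputs do and do not
emulate, and the known limitations of the reproduction.

## Input spike trains

Each of the `n_aff = 256` afferents is an inhomogeneous Poisson process.
The instantaneous rate r_j(t) performs a bounded walk in
[`rate_min`, `rate_max`] = [0, 90] Hz: at change points with
exponentially distributed spacing (mean 50 ms) a new slope is drawn
uniformly in ±(rate_max − rate_min)/`max_ramp_time` = ±1800 Hz/s; the
rate integrates linearly and sticks at a bound until the next change
point. This satisfies the two published constraints — the 0–90 Hz range
and the ≥50 ms ramp time between the extremes — and is fully seedable.
Sampling uses thinning against the piecewise-linear profile. Afterwards,
every empty 50 ms window of every afferent receives one spike at a
uniform position in the window, which makes "at least one spike per
50 ms" literally true and pins the per-afferent minimum mean rate at
20 Hz. The resulting population rate in 10 ms bins is ≈52 Hz (≈62 Hz
after the extra 10 Hz noise), stationary over the train, against
published values of ≈54/64 Hz with a ±3 Hz tolerance.

The pattern template is a uniformly chosen 50 ms slice of the base
train, restricted to the `n_active` pattern-coding afferents (256 in
Setups 1/3, 128 in Setups 2/4). Exactly `round(appearance_rate ×
n_sections)` sections are replaced by the template — 1,125 (25%) or 450
(10%) of the 4,500 sections of a 225 s train. The replaced sections are
drawn uniformly among all pairwise non-adjacent subsets via the standard
bijection between such subsets and unconstrained subsets of a shrunken
index set (no rejection loop). Inside a replaced section the non-active
afferents keep their stochastic spikes, so the pattern carries no rate
signature; only spike timing distinguishes it.

Noise is homogeneous Poisson at `noise_rate` on every afferent over the
whole train. Jitter displaces each embedded pattern spike by an
independent N(0, `jitter_sd`) draw; displaced spikes stay in the train at
their new time (clamped to the train's support, no wrap-around), because
physical jitter does not respect section edges. Each generation stage
(profiles, sampling, embedding, noise/jitter) has its own substream of
the configured seed, so identical configurations give byte-identical
event files.

What the generator does **not** emulate: refractoriness or spike-history
dependence inside an afferent, cross-afferent rate correlations, and the
10 µs event-transport granularity of a hardware address-event link (the
file format rounds to 1 µs, far below every model time constant).
Passing tests on these inputs therefore say nothing about detector
performance on structured natural signals — only about detection of a
timing-defined pattern under the stated noise model.

## Neuron and synapses

The soma is a leaky integrate-and-fire unit in normalised polarity:
threshold `v_thresh = 1`, baseline rest `v_rest = 0` (raised to 0.1875 in
the half-afferent setups, mirroring the smaller rest-to-threshold
distance used there: 130/160 of the full distance), reset
`v_reset = −1`, refractory 2 ms (the physical spike width),
`tau_m = 5 ms`. The hyperpolarising reset stands in for the deep
after-spike trajectory of the fast-spiking soma it abstracts; without it
the neuron double-fires inside pattern presentations, which keeps too
many synapses potentiated and produces false alarms.

Each presynaptic event at synapse j injects a current step
`w_j × unit_amp` that decays with `tau_s = 2.5 ms` (fast AMPA-like); the
4-bit efficacy enters linearly, like a binary-weighted DAC. All synapses
share the decay constant, so the population is carried as one summed
accumulator — exact for exponential kernels and O(1) per event.

Integration is exponential-Euler at `dt = 0.1 ms`; each event's deposit
carries its exact within-step decay factor, so the synaptic-current state
is independent of `dt`. Postsynaptic spikes are emitted at step
boundaries (pre-before-post within a step, so a coincident pre/post pair
counts as potentiation, matching the equality branch of the rule).
Open-loop (learning frozen), halving `dt` changes a run's spike count by
<2%. Closed-loop trajectories are chaotic — a one-step shift of one
postsynaptic spike reorders later pairings — so convergence in `dt` is
only meaningful open-loop.

`unit_amp = 1.3` is calibrated, as the published procedure prescribes, so
that each setup's initial efficacy (5/4/6/4) drives the soma at 40–200 Hz
during the first seconds of a run (measured: ≈55/49/133/89 Hz for
Setups 1–4). With `tau_m = 5 ms` this puts the steady-state depolarisation
just above threshold initially and just below it once depression begins —
the fluctuation-driven regime a coincidence detector needs. The membrane
constant itself was chosen by a feasibility argument (reproduced in the
test suite's spirit by `scripts/`-independent experiments): freezing
learning and hand-placing the weights that a perfect learner would find
shows that at `tau_m = 10 ms` *no* weight configuration detects the
pattern without false alarms at 256 afferents, while at 5 ms a band of
configurations (≈25–45 saturated synapses) achieves hit rate 1 with zero
false alarms. Larger (6–8 ms) and smaller (3–4 ms) values shrink that
band again.

## Plasticity

Rectangular windows, single-bit saturating updates, most-recent-pair
semantics: a presynaptic spike is stored (overwriting the previous one)
and stays *armed* until it pairs with one postsynaptic spike within
`t_pre`; a postsynaptic spike re-arms the depression latch of every
synapse, and the first presynaptic spike of a synapse within `t_post`
afterwards consumes it for −1. `t_post` is evaluated at the presynaptic
(decision) instant. The pure-Python engine, the numba kernel and an
O(n²) brute-force replay with independently derived pairing logic are
checked against each other exactly, including duplicate-timestamp
orderings.

Window constants: `t_pre = 5 ms`, `t_post_init = 1.1 × t_pre = 5.5 ms`
(the initial depression/potentiation voltage offset of the hardware is
≈8% under a subthreshold-exponential voltage-to-time map),
`t_post_final` = 26 ms (Setups 1/2), 17 ms (3), 15 ms (4) — preserving
the published per-setup ordering of the final depression voltage — and
`t_adapt = 100 s`. The default adaptation shape is the exponential ramp
(fast early rise, exact final value at `t_adapt`); linear and stepwise
are selectable. The published account states the shape is unimportant as
long as adaptation is slow; in this implementation the exponential ramp
measurably outperforms the linear one because background pruning
completes before the scoring window opens.

Why short windows: with 256 afferents at ≈54 Hz, a 16 ms potentiation
window is "hit" by ≈58% of all afferents before any postsynaptic spike —
potentiation would be indiscriminate and no selectivity can form. At
5 ms the hit probability drops to ≈24% for background afferents while
remaining ≈1 for afferents whose pattern spike causally precedes the
locked firing phase; that contrast is what the rule amplifies. The same
number controls backtracking: short windows stop the firing phase from
migrating to the very start of the pattern, so the learned latency
settles in the tens of milliseconds instead of shrinking monotonically.

## Evaluation

A postsynaptic spike is a hit iff it falls in [start, start + 50 ms) of
some pattern presentation (no margin). Hit rate is counted over
presentations starting inside the scoring window (default: final third
of the run); spikes inside a straddling presentation are never false
alarms. Success requires hit rate strictly above 98% and exactly zero
false alarms. A run with no spikes at all in the window is *failed*.
Run classes follow the published breakdown with precedence
failed > perfect > high > hits-with-FA > low-hit; sub-94% hit rates
without false alarms are folded into the low-hit class (the published
table leaves that cell empty).

## Calibration outcome and limitations

With the defaults above, the simulator reproduces

- the generator statistics (occurrence counts exactly; population rates
  and jitter sd within their stated tolerances),
- the qualitative learning signatures: high initial firing that collapses
  as selectivity emerges, bimodal final efficacies, within-pattern
  latency stabilising at a few tens of ms, and the difficulty ordering
  Setup 1 ≥ Setup 3 ≥ Setup 4 at both appearance rates,
- the published *failure phenomenology* of the ideal model: among
  non-successful runs most achieve perfect hit rates and are spoiled by a
  handful of false alarms in the last 75 s.

It does **not** reach the published ideal-model success rates: Setup 1
attains ≈35–50% (25% rate) and ≈30–40% (10% rate) against 90%/82%, and
Setup 3 ≈5–15% against 64%. The best learned states sit at the edge of
the feasibility band described above; residual false alarms are genuine
Poisson coincidence-tail events of the surviving high-weight synapses,
and the remaining failures are runs whose depression overshoots and
silences the neuron. Extensive scans over every exposed constant
(membrane and synaptic time constants, both windows, all three schedule
shapes, adaptation time, drive scale, reset depth) plateau at this
level. The likeliest unmodelled ingredient is the reference soma itself:
the hardware-equivalent ideal model uses a qualitative Class-1 neuron
whose near-threshold dynamics discriminate a coincident packet from
background more sharply than any LIF parameterisation; the reference
simulation's numeric window constants are also unpublished. The mean
fraction of fully saturated weights on successful runs is ≈0.85 here,
slightly below the ≳0.9 suggested by the published efficacy histograms —
the ±1 churn of rectangular windows continuously repopulates mid-range
weights.

Problem sizes used by the test suite and the acceptance script: unit
tests run on 5–20 s trains with 16–64 afferents; the learning batches use
full 225 s runs — 10–20 per condition in the tests, 50 per condition (the
study's own batch size) in `scripts/acceptance.py`.
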