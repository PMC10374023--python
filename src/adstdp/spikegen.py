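"""Stochastic spike-train generator with embedded repeating patterns.

Each of the ``n_aff`` afferents fires as an inhomogeneous Poisson process
whose instantaneous rate wanders inside [rate_min, rate_max] Hz with a
bounded slope, and is forced to spike at least once in every
``min_activity_window``.  A randomly chosen ``section_len`` slice of the
resulting train (restricted to the active afferents) becomes the pattern
template; it replaces a fraction ``appearance_rate`` of the non-adjacent
50 ms sections.  Optionally, homogeneous Poisson noise is superimposed on
every afferent and the pattern spikes receive Gaussian timing jitter.

The pattern carries no rate signature: inside and outside the pattern the
population rate is statistically identical, so the only cue available to a
downstream detector is the precise spatiotemporal arrangement of spikes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ._kernels import build_rate_breakpoints
from .config import ConfigurationError, GeneratorConfig

__all__ = [
    "RateProfile",
    "SpikeTrain",
    "PatternSpec",
    "build_rate_profiles",
    "sample_base_train",
    "embed_patterns",
    "apply_noise_and_jitter",
    "generate",
    "population_rate",
    "per_afferent_rates",
    "write_events",
    "read_events",
    "write_pattern_spec",
    "read_pattern_spec",
]

_MEAN_SEGMENT = 0.050  # s, mean holding time of one slope draw

TIME_DECIMALS = 6  # event files are written at 1 us resolution


class ParseError(ValueError):
    """Raised for malformed event files; message names the offending line."""


@dataclass
class RateProfile:
    """Piecewise-linear instantaneous rates r_j(t), one profile per afferent."""

    bp_t: np.ndarray       # (n_aff, max_pts) breakpoint times
    bp_r: np.ndarray       # (n_aff, max_pts) breakpoint rates
    n_pts: np.ndarray      # (n_aff,) valid points per afferent
    duration: float

    @property
    def n_aff(self) -> int:
        return self.bp_t.shape[0]

    def evaluate(self, j: int, times: np.ndarray) -> np.ndarray:
        """Rate of afferent j at the given times (linear interpolation)."""
        n = self.n_pts[j]
        return np.interp(times, self.bp_t[j, :n], self.bp_r[j, :n])


@dataclass
class SpikeTrain:
    """Address-event spike list, kept sorted by (time, afferent id)."""

    ids: np.ndarray                      # int32 afferent ids
    times: np.ndarray                    # float64 seconds
    n_aff: int
    duration: float
    pattern_mask: Optional[np.ndarray] = None  # True for embedded pattern spikes

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.ids.shape != self.times.shape:
            raise ValueError("ids and times must have equal length")

    @property
    def n_events(self) -> int:
        return self.times.shape[0]

    def sorted(self) -> "SpikeTrain":
        order = np.lexsort((self.ids, self.times))
        mask = self.pattern_mask[order] if self.pattern_mask is not None else None
        return SpikeTrain(self.ids[order], self.times[order],
                          self.n_aff, self.duration, mask)

    def spikes_of(self, j: int) -> np.ndarray:
        return np.sort(self.times[self.ids == j])


@dataclass
class PatternSpec:
    """The repeated template, where it occurs and which afferents carry it."""

    template_ids: np.ndarray       # int32 afferent ids of template spikes
    template_offsets: np.ndarray   # float64 offsets in [0, section_len)
    occurrences: np.ndarray        # float64 section start times
    active_ids: np.ndarray         # int32 afferents encoding the pattern
    section_len: float = 0.050

    @property
    def n_occurrences(self) -> int:
        return self.occurrences.shape[0]


def _spawn(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def build_rate_profiles(cfg: GeneratorConfig, rng) -> RateProfile:
    """Sample one bounded rate walk per afferent.

    Per afferent the slope is redrawn uniformly in +-max_slope at
    change points with exponentially distributed spacing (mean 50 ms); the
    rate integrates linearly and sticks at a bound until the next change
    point, so both the range and the ramp-time bound hold everywhere.
    """
    cfg.validate()
    rng = _spawn(rng)
    if cfg.duration == 0:
        bp = np.zeros((cfg.n_aff, 2))
        bp_r = np.full((cfg.n_aff, 2), cfg.rate_min)
        return RateProfile(bp, bp_r, np.full(cfg.n_aff, 2, dtype=np.int64), 0.0)

    n_seg_guess = int(cfg.duration / _MEAN_SEGMENT * 1.6) + 16
    max_pts = 2 * n_seg_guess + 4
    bp_t = np.zeros((cfg.n_aff, max_pts))
    bp_r = np.zeros((cfg.n_aff, max_pts))
    n_pts = np.zeros(cfg.n_aff, dtype=np.int64)
    s_max = cfg.max_slope

    for j in range(cfg.n_aff):
        while True:
            durations = rng.exponential(_MEAN_SEGMENT, n_seg_guess)
            if durations.sum() >= cfg.duration:
                break
        slopes = rng.uniform(-s_max, s_max, n_seg_guess)
        r0 = rng.uniform(cfg.rate_min, cfg.rate_max)
        n_pts[j] = build_rate_breakpoints(
            r0, durations, slopes, cfg.rate_min, cfg.rate_max,
            cfg.duration, bp_t[j], bp_r[j],
        )
    return RateProfile(bp_t, bp_r, n_pts, cfg.duration)


def sample_base_train(profiles: RateProfile, cfg: GeneratorConfig, rng) -> SpikeTrain:
    """Inhomogeneous Poisson sampling (thinning) + minimum-activity fill.

    After thinning against the rate profile, every empty
    ``min_activity_window`` of every afferent receives one spike at a
    uniform time inside the window, which enforces the >=1 spike / 50 ms
    guarantee (hence a mean rate of at least 20 Hz per afferent).
    """
    cfg.validate()
    rng = _spawn(rng)
    duration = cfg.duration
    if duration == 0:
        return SpikeTrain(np.empty(0, np.int32), np.empty(0), cfg.n_aff, 0.0)

    win = cfg.min_activity_window
    n_win = int(np.floor(duration / win + 1e-9))
    all_ids: list[np.ndarray] = []
    all_times: list[np.ndarray] = []
    for j in range(cfg.n_aff):
        n_cand = rng.poisson(cfg.rate_max * duration) if cfg.rate_max > 0 else 0
        if n_cand > 0:
            t_cand = rng.uniform(0.0, duration, n_cand)
            u = rng.uniform(0.0, cfg.rate_max, n_cand)
            r = profiles.evaluate(j, t_cand)
            t_keep = t_cand[u < r]
        else:
            t_keep = np.empty(0)
        if n_win > 0:
            counts = np.bincount(
                np.minimum((t_keep / win).astype(np.int64), n_win - 1),
                minlength=n_win,
            )
            empty = np.nonzero(counts == 0)[0]
            if empty.size:
                fill = (empty + rng.uniform(0.0, 1.0, empty.size)) * win
                t_keep = np.concatenate([t_keep, fill])
        all_times.append(t_keep)
        all_ids.append(np.full(t_keep.size, j, dtype=np.int32))

    train = SpikeTrain(np.concatenate(all_ids), np.concatenate(all_times),
                       cfg.n_aff, duration)
    return train.sorted()


def _sample_nonadjacent_sections(n_sections: int, k: int, rng) -> np.ndarray:
    """Uniform sample of k pairwise non-adjacent sections out of n_sections.

    Uses the standard bijection between k-subsets with no two consecutive
    elements of {0..n-1} and k-subsets of {0..n-k}: draw the latter, sort,
    and add 0,1,..,k-1.
    """
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > (n_sections + 1) // 2:
        raise ConfigurationError(
            f"appearance_rate too high: cannot place {k} non-adjacent "
            f"sections among {n_sections}"
        )
    base = np.sort(rng.choice(n_sections - k + 1, size=k, replace=False))
    return base + np.arange(k)


def embed_patterns(train: SpikeTrain, cfg: GeneratorConfig, rng):
    """Copy a random 50 ms slice and paste it into non-adjacent sections.

    Returns ``(train_with_patterns, PatternSpec)``.  Only the
    ``n_active`` randomly chosen afferents carry the template; inside the
    replaced sections the remaining afferents keep their original spikes.
    """
    cfg.validate()
    rng = _spawn(rng)
    n_sections = cfg.n_sections
    k = int(round(cfg.appearance_rate * n_sections))
    L = cfg.section_len

    active_ids = np.sort(rng.choice(cfg.n_aff, size=cfg.n_active,
                                    replace=False)).astype(np.int32)
    if k == 0:
        spec = PatternSpec(np.empty(0, np.int32), np.empty(0),
                           np.empty(0), active_ids, L)
        out = replace(train)
        out.pattern_mask = np.zeros(train.n_events, dtype=bool)
        return out, spec

    # template: a uniformly chosen section of the base train, active afferents only
    src = int(rng.integers(n_sections))
    s0 = src * L
    active_mask = np.zeros(cfg.n_aff, dtype=bool)
    active_mask[active_ids] = True
    in_src = (train.times >= s0) & (train.times < s0 + L) & active_mask[train.ids]
    template_ids = train.ids[in_src].copy()
    template_offsets = train.times[in_src] - s0

    sections = _sample_nonadjacent_sections(n_sections, k, rng)
    occurrences = sections * L

    # drop active-afferent spikes inside the chosen sections
    sec_idx = np.minimum((train.times / L).astype(np.int64), n_sections - 1)
    chosen = np.zeros(n_sections, dtype=bool)
    chosen[sections] = True
    drop = chosen[sec_idx] & active_mask[train.ids]

    keep_ids = train.ids[~drop]
    keep_times = train.times[~drop]
    ins_ids = np.tile(template_ids, k)
    ins_times = (occurrences[:, None] + template_offsets[None, :]).ravel()

    ids = np.concatenate([keep_ids, ins_ids])
    times = np.concatenate([keep_times, ins_times])
    mask = np.concatenate([np.zeros(keep_ids.size, dtype=bool),
                           np.ones(ins_ids.size, dtype=bool)])
    out = SpikeTrain(ids, times, train.n_aff, train.duration, mask).sorted()
    spec = PatternSpec(template_ids, template_offsets, occurrences.astype(float),
                       active_ids, L)
    return out, spec


def apply_noise_and_jitter(train: SpikeTrain, spec: PatternSpec,
                           cfg: GeneratorConfig, rng) -> SpikeTrain:
    """Add homogeneous Poisson noise and jitter the embedded pattern spikes.

    Noise spikes at ``noise_rate`` Hz are superimposed on every afferent
    over the full duration.  Each pattern spike is displaced by an
    independent N(0, jitter_sd) draw; displaced spikes stay in the train at
    their new time even if they leave their 50 ms section (clamped to the
    train's [0, duration) support).
    """
    cfg.validate()
    rng = _spawn(rng)
    if cfg.noise_rate == 0 and cfg.jitter_sd == 0:
        return train

    times = train.times.copy()
    ids = train.ids.copy()
    mask = (train.pattern_mask.copy() if train.pattern_mask is not None
            else np.zeros(train.n_events, dtype=bool))

    if cfg.jitter_sd > 0 and mask.any():
        n_pat = int(mask.sum())
        times[mask] = np.clip(times[mask] + rng.normal(0.0, cfg.jitter_sd, n_pat),
                              0.0, np.nextafter(train.duration, 0.0))

    if cfg.noise_rate > 0 and train.duration > 0:
        n_noise = rng.poisson(cfg.noise_rate * train.duration * train.n_aff)
        noise_ids = rng.integers(0, train.n_aff, n_noise).astype(np.int32)
        noise_times = rng.uniform(0.0, train.duration, n_noise)
        ids = np.concatenate([ids, noise_ids])
        times = np.concatenate([times, noise_times])
        mask = np.concatenate([mask, np.zeros(n_noise, dtype=bool)])

    return SpikeTrain(ids, times, train.n_aff, train.duration, mask).sorted()


def generate(cfg: GeneratorConfig):
    """Full generation pipeline; returns ``(SpikeTrain, PatternSpec)``.

    The configured seed is expanded into independent substreams for the
    rate profiles, Poisson sampling, pattern embedding and noise/jitter, so
    identical configurations reproduce byte-identical event files.
    """
    cfg.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    profiles = build_rate_profiles(cfg, streams[0])
    base = sample_base_train(profiles, cfg, streams[1])
    with_patterns, spec = embed_patterns(base, cfg, streams[2])
    final = apply_noise_and_jitter(with_patterns, spec, cfg, streams[3])
    return final, spec


def population_rate(train: SpikeTrain, bin_width: float = 0.010) -> np.ndarray:
    """Population-averaged firing rate (Hz) in consecutive time bins."""
    n_bins = int(np.floor(train.duration / bin_width + 1e-9))
    if n_bins == 0:
        return np.empty(0)
    idx = np.minimum((train.times / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / (train.n_aff * bin_width)


def per_afferent_rates(train: SpikeTrain) -> np.ndarray:
    """Mean firing rate (Hz) of each afferent over the whole train."""
    counts = np.bincount(train.ids, minlength=train.n_aff)
    return counts / train.duration


# ---------------------------------------------------------------------------
# event-file I/O: headered CSV at 1 us time resolution
# ---------------------------------------------------------------------------

def write_events(train: SpikeTrain, path) -> None:
    """Write a time-sorted ``afferent_id,time_s`` CSV with metadata header."""
    train = train.sorted()
    buf = _io.StringIO()
    buf.write(f"#n_aff={train.n_aff}\n")
    buf.write(f"#duration_s={train.duration:.6f}\n")
    for j, t in zip(train.ids, train.times):
        buf.write(f"{j},{t:.{TIME_DECIMALS}f}\n")
    Path(path).write_text(buf.getvalue())


def read_events(path) -> SpikeTrain:
    """Read an event file written by :func:`write_events`, validating rows."""
    lines = Path(path).read_text().splitlines()
    n_aff = None
    duration = None
    ids: list[int] = []
    times: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "n_aff":
                n_aff = int(value)
            elif key == "duration_s":
                duration = float(value)
            else:
                raise ParseError(f"line {lineno}: unknown header {key!r}")
            continue
        if n_aff is None or duration is None:
            raise ParseError(f"line {lineno}: data before complete header")
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'afferent_id,time_s'")
        try:
            j = int(parts[0])
            t = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if not (0 <= j < n_aff):
            raise ParseError(
                f"line {lineno}: afferent_id {j} out of range [0, {n_aff})"
            )
        if not (0.0 <= t < duration + 1e-9) and duration > 0:
            raise ParseError(f"line {lineno}: time {t} outside [0, {duration})")
        ids.append(j)
        times.append(t)
    if n_aff is None or duration is None:
        raise ParseError("missing #n_aff / #duration_s header")
    return SpikeTrain(np.array(ids, np.int32), np.array(times),
                      n_aff, duration).sorted()


def write_pattern_spec(spec: PatternSpec, template_path, occurrences_path) -> None:
    with open(template_path, "w") as fh:
        fh.write("#section_len_s=%.6f\n" % spec.section_len)
        fh.write("#active_ids=%s\n" % ";".join(str(i) for i in spec.active_ids))
        for j, off in zip(spec.template_ids, spec.template_offsets):
            fh.write(f"{j},{off:.{TIME_DECIMALS}f}\n")
    with open(occurrences_path, "w") as fh:
        for s in spec.occurrences:
            fh.write(f"{s:.{TIME_DECIMALS}f}\n")


def read_pattern_spec(template_path, occurrences_path) -> PatternSpec:
    section_len = 0.050
    active: list[int] = []
    t_ids: list[int] = []
    t_off: list[float] = []
    for lineno, line in enumerate(Path(template_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "section_len_s":
                section_len = float(value)
            elif key == "active_ids":
                active = [int(x) for x in value.split(";") if x]
            continue
        j_str, _, off_str = line.partition(",")
        t_ids.append(int(j_str))
        t_off.append(float(off_str))
    occ = [float(line) for line in
           Path(occurrences_path).read_text().split() if line]
    return PatternSpec(np.array(t_ids, np.int32), np.array(t_off),
                       np.array(occ), np.array(active, np.int32), section_len)
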