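"""Generator contracts: rate-walk bounds, minimum activity, pattern
embedding, noise/jitter statistics and event-file round trips."""

import dataclasses

import numpy as np
import pytest

from adstdp import spikegen
from adstdp.config import ConfigurationError, GeneratorConfig
from adstdp.spikegen import (ParseError, PatternSpec, SpikeTrain,
                             apply_noise_and_jitter, build_rate_profiles,
                             embed_patterns, generate, per_afferent_rates,
                             population_rate, read_events, sample_base_train,
                             write_events)


class TestRateProfiles:
    def test_range_and_slope_bounds_on_1ms_grid(self, small_cfg, rng):
        prof = build_rate_profiles(small_cfg, rng)
        grid = np.arange(0.0, small_cfg.duration, 0.001)
        for j in range(small_cfg.n_aff):
            r = prof.evaluate(j, grid)
            assert r.min() >= small_cfg.rate_min - 1e-9
            assert r.max() <= small_cfg.rate_max + 1e-9
            slope = np.abs(np.diff(r)) / 0.001
            assert slope.max() <= small_cfg.max_slope * (1 + 1e-6)

    def test_degenerate_bounds_force_flat_profile(self, rng):
        cfg = GeneratorConfig(n_aff=4, n_active=4, duration=2.0,
                              rate_min=20.0, rate_max=20.0)
        prof = build_rate_profiles(cfg, rng)
        grid = np.linspace(0.0, 2.0, 200)
        for j in range(4):
            assert np.allclose(prof.evaluate(j, grid), 20.0)

    def test_long_run_average_matches_monte_carlo_of_walk(self, rng):
        # the stationary mean of the clipped walk, estimated over many
        # independent profiles, should be reproduced by fresh draws
        cfg = GeneratorConfig(n_aff=300, n_active=300, duration=30.0)
        grid = np.arange(0.0, 30.0, 0.005)
        prof = build_rate_profiles(cfg, rng)
        means_a = [prof.evaluate(j, grid).mean() for j in range(cfg.n_aff)]
        prof2 = build_rate_profiles(cfg, np.random.default_rng(999))
        means_b = [prof2.evaluate(j, grid).mean() for j in range(cfg.n_aff)]
        assert abs(np.mean(means_a) - np.mean(means_b)) < 2.0  # Hz

    def test_invalid_config_raises(self, rng):
        cfg = GeneratorConfig(rate_min=100.0, rate_max=90.0)
        with pytest.raises(ConfigurationError):
            build_rate_profiles(cfg, rng)


class TestBaseTrain:
    def test_minimum_activity_every_window(self, small_cfg, rng):
        prof = build_rate_profiles(small_cfg, rng)
        train = sample_base_train(prof, small_cfg, rng)
        win = small_cfg.min_activity_window
        n_win = int(round(small_cfg.duration / win))
        for j in range(small_cfg.n_aff):
            t = train.spikes_of(j)
            counts = np.bincount(np.minimum((t / win).astype(int), n_win - 1),
                                 minlength=n_win)
            assert counts.min() >= 1

    def test_minimum_mean_rate_20hz(self, small_cfg, rng):
        prof = build_rate_profiles(small_cfg, rng)
        train = sample_base_train(prof, small_cfg, rng)
        assert per_afferent_rates(train).min() >= 1.0 / small_cfg.min_activity_window

    def test_zero_duration_gives_empty_train(self, rng):
        cfg = GeneratorConfig(n_aff=8, n_active=8, duration=0.0)
        prof = build_rate_profiles(cfg, rng)
        train = sample_base_train(prof, cfg, rng)
        assert train.n_events == 0

    def test_population_rate_is_stationary(self):
        train, _ = generate(GeneratorConfig(n_aff=128, n_active=128,
                                            duration=90.0, seed=5))
        rates = population_rate(train, 0.010)
        third = rates.size // 3
        first, last = rates[:third].mean(), rates[-third:].mean()
        assert abs(first - last) / first < 0.05


class TestEmbedding:
    def test_occurrence_count_grid_and_non_adjacency(self, small_cfg, rng):
        prof = build_rate_profiles(small_cfg, rng)
        train = sample_base_train(prof, small_cfg, rng)
        out, spec = embed_patterns(train, small_cfg, rng)
        n_expected = round(small_cfg.appearance_rate * small_cfg.n_sections)
        assert spec.n_occurrences == n_expected
        sections = np.round(spec.occurrences / small_cfg.section_len).astype(int)
        assert np.allclose(spec.occurrences, sections * small_cfg.section_len)
        assert np.diff(np.sort(sections)).min() >= 2

    def test_template_exact_inside_every_occurrence(self, rng):
        cfg = GeneratorConfig(n_aff=24, n_active=12, duration=10.0,
                              appearance_rate=0.2)
        prof = build_rate_profiles(cfg, rng)
        train = sample_base_train(prof, cfg, rng)
        out, spec = embed_patterns(train, cfg, rng)
        active = set(spec.active_ids.tolist())
        tmpl = sorted(zip(spec.template_ids.tolist(),
                          np.round(spec.template_offsets, 9).tolist()))
        for s in spec.occurrences:
            in_occ = (out.times >= s) & (out.times < s + cfg.section_len)
            ids = out.ids[in_occ]
            offs = out.times[in_occ] - s
            got = sorted((i, round(o, 9)) for i, o in zip(ids, offs)
                         if i in active)
            assert got == tmpl

    def test_non_active_afferents_untouched_in_occurrences(self, rng):
        cfg = GeneratorConfig(n_aff=24, n_active=12, duration=10.0,
                              appearance_rate=0.2)
        prof = build_rate_profiles(cfg, rng)
        train = sample_base_train(prof, cfg, rng)
        out, spec = embed_patterns(train, cfg, rng)
        inactive = sorted(set(range(cfg.n_aff)) - set(spec.active_ids.tolist()))
        for j in inactive:
            assert np.array_equal(train.spikes_of(j), out.spikes_of(j))

    def test_zero_appearance_rate_is_identity(self, small_cfg, rng):
        cfg = dataclasses.replace(small_cfg, appearance_rate=0.0)
        prof = build_rate_profiles(cfg, rng)
        train = sample_base_train(prof, cfg, rng)
        out, spec = embed_patterns(train, cfg, rng)
        assert spec.n_occurrences == 0
        assert np.array_equal(out.times, train.times)

    def test_infeasible_appearance_rate_raises(self, rng):
        cfg = GeneratorConfig(n_aff=8, n_active=8, duration=1.0,
                              appearance_rate=0.8)
        prof = build_rate_profiles(cfg, rng)
        train = sample_base_train(prof, cfg, rng)
        with pytest.raises(ConfigurationError):
            embed_patterns(train, cfg, rng)


class TestNoiseAndJitter:
    def test_identity_when_disabled(self, tiny_cfg, rng):
        prof = build_rate_profiles(tiny_cfg, rng)
        train = sample_base_train(prof, tiny_cfg, rng)
        out, spec = embed_patterns(train, tiny_cfg, rng)
        final = apply_noise_and_jitter(out, spec, tiny_cfg, rng)
        assert final is out

    def test_noise_raises_population_rate_by_noise_rate(self, rng):
        cfg = GeneratorConfig(n_aff=64, n_active=64, duration=60.0,
                              appearance_rate=0.25, seed=11)
        train, spec = generate(cfg)
        base_rate = population_rate(train).mean()
        noisy_cfg = dataclasses.replace(cfg, noise_rate=10.0)
        noisy = apply_noise_and_jitter(train, spec, noisy_cfg,
                                       np.random.default_rng(1))
        noisy_rate = population_rate(noisy).mean()
        assert noisy_rate - base_rate == pytest.approx(10.0, abs=1.0)

    def test_jitter_displacement_sd(self, rng):
        # synthetic train where every pattern spike is isolated, so the
        # displacement of each spike is unambiguous
        n_aff, n_occ = 256, 100
        occurrences = np.arange(n_occ) * 0.1
        offsets = np.linspace(0.001, 0.049, n_aff)
        ids = np.tile(np.arange(n_aff, dtype=np.int32), n_occ)
        times = (occurrences[:, None] + offsets[None, :]).ravel()
        train = SpikeTrain(ids, times, n_aff, 10.0,
                           pattern_mask=np.ones(times.size, dtype=bool))
        spec = PatternSpec(np.arange(n_aff, dtype=np.int32), offsets,
                           occurrences, np.arange(n_aff, dtype=np.int32))
        cfg = GeneratorConfig(n_aff=n_aff, n_active=n_aff, duration=10.0,
                              section_len=0.1, jitter_sd=0.001)
        out = apply_noise_and_jitter(train, spec, cfg, rng)
        disp = []
        for j in range(n_aff):
            disp.extend(out.spikes_of(j) - train.spikes_of(j))
        disp = np.asarray(disp)
        assert disp.size >= 10_000
        assert disp.std() == pytest.approx(0.001, abs=0.0001)
        assert abs(disp.mean()) < 5e-5


class TestEventIO:
    def test_round_trip_identity(self, tiny_cfg, rng, tmp_path):
        train, _ = generate(tiny_cfg)
        path = tmp_path / "events.csv"
        write_events(train, path)
        back = read_events(path)
        assert back.n_aff == train.n_aff
        assert back.duration == pytest.approx(train.duration)
        assert np.array_equal(back.ids, train.sorted().ids)
        assert np.allclose(back.times, train.sorted().times, atol=1e-6)

    def test_seeded_determinism_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(n_aff=16, n_active=16, duration=5.0, seed=42,
                              noise_rate=10.0, jitter_sd=0.001)
        paths = []
        for name in ("a.csv", "b.csv"):
            train, _ = generate(cfg)
            p = tmp_path / name
            write_events(train, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_out_of_range_id_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("#n_aff=256\n#duration_s=1.000000\n300,0.5\n")
        with pytest.raises(ParseError, match="line 3"):
            read_events(p)

    def test_malformed_row_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("#n_aff=4\n#duration_s=1.000000\n1;0.5\n")
        with pytest.raises(ParseError):
            read_events(p)

    def test_empty_events_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("#n_aff=8\n#duration_s=2.000000\n")
        train = read_events(p)
        assert train.n_events == 0
        assert train.duration == 2.0

    def test_pattern_spec_round_trip(self, tiny_cfg, tmp_path):
        _, spec = generate(tiny_cfg)
        spikegen.write_pattern_spec(spec, tmp_path / "t.csv", tmp_path / "o.csv")
        back = spikegen.read_pattern_spec(tmp_path / "t.csv", tmp_path / "o.csv")
        assert np.array_equal(back.template_ids, spec.template_ids)
        assert np.allclose(back.template_offsets, spec.template_offsets, atol=1e-6)
        assert np.allclose(back.occurrences, spec.occurrences, atol=1e-6)
        assert np.array_equal(back.active_ids, spec.active_ids)
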