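"""Theta-gamma schedules, cue degradation, backgrounds, training phases."""

import numpy as np
import pytest

from ca3net.network_builder import (
    AssemblySpec,
    NeuronTypeSpec,
    BackgroundCurrentSpec,
    build_network,
    round_half_up,
)
from ca3net.protocols import (
    CheckpointError,
    DegenerateCueError,
    PatternSpec,
    ScheduleConflictError,
    build_testing_schedule,
    build_training_schedule,
    compile_drive,
    degrade_pattern,
    generate_pattern,
    initial_checkpoint,
    run_test_from_checkpoint,
    run_training,
    sample_background_currents,
)

from conftest import izh_params, make_tiny_config


def make_assembly(ids, assembly_id=0, shared=None):
    return AssemblySpec(assembly_id=assembly_id, member_ids=np.asarray(ids),
                        shared_with=shared or {})


class TestGeneratePattern:
    def test_offsets_on_grid_inside_window(self):
        pat = generate_pattern(make_assembly(np.arange(30)), rng=0)
        assert pat.offsets.shape == (30, 4)
        assert np.all((pat.offsets >= 0) & (pat.offsets < 20.0))
        np.testing.assert_allclose(pat.offsets / 0.2,
                                   np.round(pat.offsets / 0.2), atol=1e-9)

    def test_zero_spikes_empty_trains(self):
        pat = generate_pattern(make_assembly(np.arange(5)), n_spikes=0, rng=0)
        assert pat.offsets.size == 0 and pat.n_spikes == 0

    def test_default_spike_count_is_four(self):
        # 4 spikes per member per presentation: 100 presentations of
        # 4-spike trains motivate the 400 in the amplitude derivation
        pat = generate_pattern(make_assembly(np.arange(100)), rng=1)
        assert pat.n_spikes == 4
        assert pat.offsets.shape[1] == 4

    def test_same_seed_same_pattern(self):
        a = generate_pattern(make_assembly(np.arange(20)), rng=5)
        b = generate_pattern(make_assembly(np.arange(20)), rng=5)
        np.testing.assert_array_equal(a.offsets, b.offsets)


class TestTrainingSchedule:
    def _patterns(self, n):
        return [generate_pattern(make_assembly(np.arange(i * 10, i * 10 + 5),
                                               assembly_id=i), rng=i)
                for i in range(n)]

    def test_three_patterns_65_presentations(self):
        sched = build_training_schedule(self._patterns(3), 65, settle_ms=1000)
        assert len(sched.entries) == 195           # 195 theta cycles
        # 39 s of patterned time within the training run
        assert sched.duration_ms - 1000 == pytest.approx(39_000)

    def test_single_presentation_single_entry(self):
        sched = build_training_schedule(self._patterns(1), 1, settle_ms=0)
        assert len(sched.entries) == 1
        assert sched.entries[0].onset_ms == 0.0

    def test_consecutive_onsets_differ_by_theta(self):
        sched = build_training_schedule(self._patterns(3), 10)
        onsets = np.array([e.onset_ms for e in sched.entries])
        np.testing.assert_allclose(np.diff(onsets), 200.0)

    def test_round_robin_order(self):
        sched = build_training_schedule(self._patterns(3), 2)
        ids = [e.stimulus.assembly_id for e in sched.entries]
        assert ids == [0, 1, 2, 0, 1, 2]

    def test_pattern_frozen_across_presentations(self):
        sched = build_training_schedule(self._patterns(2), 30)
        first = [e for e in sched.entries if e.stimulus.assembly_id == 0]
        assert all(e.stimulus is first[0].stimulus for e in first)


class TestDegradePattern:
    def test_half_of_275_is_138(self):
        pat = generate_pattern(make_assembly(np.arange(275)), rng=0)
        cue = degrade_pattern(pat, 50.0, rng=0)
        assert cue.member_ids.size == 138

    def test_overlap_proportional_split_135_15(self):
        # 300-cell assembly sharing 15 cells with each of two others:
        # a 50% cue takes 135 unique + 15 shared members
        shared = {1: np.arange(270, 285), 2: np.arange(285, 300)}
        asm = make_assembly(np.arange(300), shared=shared)
        pat = generate_pattern(asm, rng=0)
        cue = degrade_pattern(pat, 50.0, overlap_aware=True, assembly=asm, rng=0)
        assert cue.member_ids.size == 150
        n_shared = np.isin(cue.member_ids, np.arange(270, 300)).sum()
        assert n_shared == 15
        assert cue.member_ids.size - n_shared == 135

    def test_zero_degradation_full_assembly(self):
        pat = generate_pattern(make_assembly(np.arange(40)), rng=0)
        cue = degrade_pattern(pat, 0.0, rng=0)
        np.testing.assert_array_equal(np.sort(cue.member_ids),
                                      np.arange(40))

    def test_cue_subset_of_assembly_with_source_times(self):
        pat = generate_pattern(make_assembly(np.arange(100, 160)), rng=2)
        cue = degrade_pattern(pat, 70.0, rng=3)
        assert cue.member_ids.size == round_half_up(0.3 * 60)
        assert np.isin(cue.member_ids, pat.member_ids).all()
        rows = np.searchsorted(pat.member_ids, cue.member_ids)
        np.testing.assert_array_equal(cue.offsets, pat.offsets[rows])

    def test_degenerate_cue_rejected(self):
        pat = generate_pattern(make_assembly(np.arange(4)), rng=0)
        with pytest.raises(DegenerateCueError):
            degrade_pattern(pat, 95.0, rng=0)

    @pytest.mark.parametrize("bad", [-1.0, 100.0, 150.0])
    def test_invalid_degradation_rejected(self, bad):
        pat = generate_pattern(make_assembly(np.arange(10)), rng=0)
        with pytest.raises(ValueError):
            degrade_pattern(pat, bad, rng=0)


class TestTestingSchedule:
    def _cues(self, n, size=10):
        out = []
        for i in range(n):
            asm = make_assembly(np.arange(i * 100, i * 100 + size), assembly_id=i)
            pat = generate_pattern(asm, rng=i)
            out.append(degrade_pattern(pat, 50.0, rng=i))
        return out

    def test_simultaneous_at_onset_with_readout(self):
        sched = build_testing_schedule(self._cues(3), onset_ms=500.0)
        assert [e.onset_ms for e in sched.entries] == [500.0] * 3
        assert sched.readout_windows == [(500.0, 520.0)] * 3

    def test_empty_cues_empty_schedule(self):
        sched = build_testing_schedule([])
        assert sched.entries == [] and sched.readout_windows == []

    def test_sequential_mode_theta_spacing(self):
        sched = build_testing_schedule(self._cues(3), onset_ms=100.0,
                                       mode="sequential")
        onsets = [e.onset_ms for e in sched.entries]
        np.testing.assert_allclose(np.diff(onsets), 200.0)

    def test_shared_neuron_conflict_detected(self):
        asm = make_assembly(np.arange(10))
        pat = generate_pattern(asm, rng=0)
        cue_a = degrade_pattern(pat, 0.0, rng=0)
        cue_b = degrade_pattern(pat, 0.0, rng=1)
        with pytest.raises(ScheduleConflictError):
            build_testing_schedule([cue_a, cue_b])
        # merge_shared suppresses the conflict
        build_testing_schedule([cue_a, cue_b], merge_shared=True)

    def test_onset_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            build_testing_schedule(self._cues(1), onset_ms=1500.0,
                                   duration_ms=1000.0)


class TestBackgroundCurrents:
    def _spec(self, mu, sigma2, override=False):
        return NeuronTypeSpec(
            name="Pyramidal", count=10, izh=izh_params("Pyramidal"),
            background=BackgroundCurrentSpec(
                mu=mu, sigma2=sigma2,
                mu_presentation=mu if override else None,
                sigma2_presentation=1.0 if override else None),
            is_excitatory=True)

    def test_zero_variance_degenerates_to_constant(self):
        cur = sample_background_currents(self._spec(4.0, 0.0), 50, rng=0)
        np.testing.assert_allclose(cur, np.exp(4.0))

    def test_strictly_positive_support(self):
        cur = sample_background_currents(self._spec(4.0, 1.5), 10_000, rng=1)
        assert np.all(cur > 0)

    def test_log_moments_recovered(self):
        # ln(I) ~ Normal(4.0, 1.5): sample moments within 3 standard errors
        n = 100_000
        cur = sample_background_currents(self._spec(4.0, 1.5), n, rng=2)
        logs = np.log(cur)
        se_mean = np.sqrt(1.5 / n)
        se_var = 1.5 * np.sqrt(2.0 / (n - 1))
        assert abs(logs.mean() - 4.0) < 3 * se_mean
        assert abs(logs.var(ddof=1) - 1.5) < 3 * se_var

    def test_presentation_override_changes_spread(self):
        spec = self._spec(4.0, 1.5, override=True)
        base = sample_background_currents(spec, 50_000, False, rng=3)
        pres = sample_background_currents(spec, 50_000, True, rng=3)
        assert np.log(base).var() > np.log(pres).var() * 1.2


class TestTrainingPhase:
    def _setup(self, presentations, n_pc=30, size=6):
        cfg = make_tiny_config(n_pc=n_pc, n_basket=8, c_pcpc=0.6,
                               pc_sigma2=0.5)
        net = build_network(cfg, size, 2, 0.0, seed=3)
        pats = [generate_pattern(a, rng=i) for i, a in enumerate(net.assemblies)]
        sched = build_training_schedule(pats, presentations, settle_ms=200.0)
        return net, pats, sched

    def test_checkpoint_count(self):
        net, _, sched = self._setup(10)
        ckpts = run_training(net, sched, checkpoint_every=5, seed=0, forced=True)
        assert [c.presentations for c in ckpts] == [5, 10]

    def test_zero_presentations_no_checkpoints_weights_at_init(self):
        net, pats, _ = self._setup(1)
        from ca3net.protocols import StimulusSchedule

        empty = StimulusSchedule(entries=[], duration_ms=200.0)
        ckpts = run_training(net, empty, checkpoint_every=5, seed=0)
        assert ckpts == []
        assert np.all(net.plastic_weights == 0.625)

    def test_bit_identical_checkpoints_same_seed(self):
        net1, _, sched1 = self._setup(5)
        ck1 = run_training(net1, sched1, checkpoint_every=5, seed=9, forced=True)
        net2, _, sched2 = self._setup(5)
        ck2 = run_training(net2, sched2, checkpoint_every=5, seed=9, forced=True)
        np.testing.assert_array_equal(ck1[0].weights, ck2[0].weights)

    def test_resume_equals_uninterrupted(self):
        net1, _, sched1 = self._setup(10)
        ck1 = run_training(net1, sched1, checkpoint_every=5, seed=4,
                           forced=True, keep_sim_state=True)
        w_full = ck1[-1].weights
        net2, _, sched2 = self._setup(10)
        ck_first = run_training(net2, sched2, checkpoint_every=5, seed=4,
                                forced=True, keep_sim_state=True)[0]
        ck_resumed = run_training(net2, sched2, checkpoint_every=5, seed=4,
                                  forced=True, resume_from=ck_first)
        np.testing.assert_array_equal(ck_resumed[-1].weights, w_full)

    def test_training_raises_within_assembly_weights_monotonically(self):
        net, _, sched = self._setup(12, n_pc=40, size=8)
        ckpts = run_training(net, sched, checkpoint_every=4, seed=1, forced=True)
        from ca3net.metrics import _within_mask

        within = _within_mask(net)
        means = [0.625] + [c.weights[within].mean() for c in ckpts]
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestTestPhase:
    def _trained(self):
        cfg = make_tiny_config(n_pc=30, n_basket=8, c_pcpc=0.6, pc_sigma2=0.5)
        net = build_network(cfg, 6, 2, 0.0, seed=3)
        pats = [generate_pattern(a, rng=i) for i, a in enumerate(net.assemblies)]
        sched = build_training_schedule(pats, 5, settle_ms=200.0)
        ckpts = run_training(net, sched, checkpoint_every=5, seed=0, forced=True)
        return net, pats, ckpts[-1]

    def test_mean_weight_equals_w_init_exactly_after_downscale(self):
        net, pats, ckpt = self._trained()
        cues = [degrade_pattern(p, 50.0, rng=i) for i, p in enumerate(pats)]
        run_test_from_checkpoint(net, ckpt, cues, seed=0)
        assert net.plastic_weights.mean() == pytest.approx(0.625, rel=1e-12)

    def test_untrained_checkpoint_downscale_is_noop(self):
        cfg = make_tiny_config(n_pc=20, n_basket=5)
        net = build_network(cfg, 5, 1, 0.0, seed=0)
        ckpt = initial_checkpoint(net)
        pats = [generate_pattern(net.assemblies[0], rng=0)]
        cues = [degrade_pattern(pats[0], 50.0, rng=0)]
        result = run_test_from_checkpoint(net, ckpt, cues, seed=0)
        assert result.downscale_factor == pytest.approx(1.0)

    def test_identical_seed_identical_raster(self):
        net, pats, ckpt = self._trained()
        cues = [degrade_pattern(p, 50.0, rng=i) for i, p in enumerate(pats)]
        r1 = run_test_from_checkpoint(net, ckpt, cues, seed=5)
        r2 = run_test_from_checkpoint(net, ckpt, cues, seed=5)
        np.testing.assert_array_equal(r1.record.times, r2.record.times)
        np.testing.assert_array_equal(r1.record.neuron_ids, r2.record.neuron_ids)

    def test_config_hash_mismatch_rejected(self):
        net, pats, ckpt = self._trained()
        other_cfg = make_tiny_config(n_pc=31, n_basket=8, c_pcpc=0.6,
                                     pc_sigma2=0.5)
        other = build_network(other_cfg, 6, 2, 0.0, seed=3)
        cues = [degrade_pattern(pats[0], 50.0, rng=0)]
        with pytest.raises(CheckpointError):
            run_test_from_checkpoint(other, ckpt, cues, seed=0)


class TestCompileDrive:
    def test_forced_spikes_land_on_commanded_times(self):
        asm = make_assembly(np.arange(3))
        pat = generate_pattern(asm, rng=0)
        sched = build_training_schedule([pat], 2, settle_ms=100.0)
        drive = compile_drive(sched, forced=True)
        # emission time = (step + 1) * dt reproduces onset + offset exactly
        expected = np.sort(np.concatenate(
            [e.onset_ms + e.stimulus.offsets.ravel() for e in sched.entries]))
        got = np.sort((drive.pulse_steps + 1) * 0.2)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_presentation_windows_cover_entries(self):
        asm = make_assembly(np.arange(3))
        pat = generate_pattern(asm, rng=0)
        sched = build_training_schedule([pat], 3, settle_ms=100.0)
        drive = compile_drive(sched)
        assert drive.presentation_windows.shape == (3, 2)
        np.testing.assert_array_equal(
            drive.presentation_windows[:, 1] - drive.presentation_windows[:, 0],
            np.full(3, 100))
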