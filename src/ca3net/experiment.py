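"""End-to-end experiment orchestration.

Binds the stages together: build a network at a chosen scale, train it on
theta-gamma patterns with symmetric STDP, checkpoint the plastic weights,
downscale, test pattern completion from degraded cues, and compute the
reconstruction/auto-association metrics.  All randomness is derived from a
single experiment seed, split by role (wiring, patterns, training
background, cue selection, test background) so each source can be varied
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as m
from .dynamics_engine import SpikeRecord
from .network_builder import (
    NetworkConfig,
    NetworkInstance,
    build_network,
)
from .metrics import ActivityVector, MetricsReport
from .protocols import (
    Checkpoint,
    CueSpec,
    PatternSpec,
    build_training_schedule,
    degrade_pattern,
    generate_pattern,
    initial_checkpoint,
    run_test_from_checkpoint,
    run_training,
)

__all__ = ["ExperimentSeeds", "TestOutcome", "ExperimentResult",
           "derive_seeds", "train_assemblies", "evaluate_checkpoint",
           "run_completion_experiment"]


@dataclass(frozen=True)
class ExperimentSeeds:
    """Role-separated child seeds derived from one experiment seed."""

    wiring: int
    patterns: int
    train_background: int
    cues: int
    test_background: int


def derive_seeds(seed: int) -> ExperimentSeeds:
    state = np.random.SeedSequence(seed).generate_state(5) & 0x7FFFFFFF
    return ExperimentSeeds(*(int(s) for s in state))


@dataclass
class TestOutcome:
    presentations: int
    degradation_pct: float
    report: MetricsReport


@dataclass
class ExperimentResult:
    network: NetworkInstance
    patterns: list[PatternSpec]
    checkpoints: list[Checkpoint]
    train_record: SpikeRecord
    train_out_windows: list[tuple[float, float]]
    tests: list[TestOutcome] = field(default_factory=list)

    def learning_table(self):
        import pandas as pd

        return pd.DataFrame([
            {"presentations": t.presentations,
             "degradation_pct": t.degradation_pct,
             "accuracy_mean": t.report.accuracy_mean,
             "snr": t.report.snr,
             "pct_at_max": t.report.pct_at_max}
            for t in self.tests
        ])


def _indicator(member_ids: np.ndarray, pc_ids: np.ndarray) -> ActivityVector:
    values = np.isin(pc_ids, member_ids).astype(float)
    return ActivityVector(neuron_ids=pc_ids, values=values, window=(0.0, 0.0))


def train_assemblies(
    config: NetworkConfig,
    assembly_size: int,
    n_assemblies: int = 3,
    overlap_fraction: float = 0.0,
    presentations: int = 30,
    checkpoint_every: int = 5,
    seed: int = 0,
    settle_ms: float = 1000.0,
    n_spikes: int = 4,
    dt: float = 0.2,
    forced: bool = False,
    keep_sim_state: bool = False,
):
    """Build, pattern and train a network; return it with its checkpoints.

    The training spike raster is kept so that training-output activity
    vectors (who fired during the final presentation of each pattern) are
    available to the reconstruction metric.
    """
    seeds = derive_seeds(seed)
    network = build_network(config, assembly_size, n_assemblies,
                            overlap_fraction, seed=seeds.wiring)
    pat_rng = np.random.default_rng(seeds.patterns)
    patterns = [generate_pattern(a, n_spikes=n_spikes, rng=pat_rng, dt=dt)
                for a in network.assemblies]
    schedule = build_training_schedule(patterns, presentations,
                                       settle_ms=settle_ms)
    checkpoints, record = run_training(
        network, schedule, checkpoint_every=checkpoint_every, dt=dt,
        seed=seeds.train_background, forced=forced,
        keep_sim_state=keep_sim_state, return_record=True)
    # training-output window: the stimulation gamma window of the final
    # presentation of each pattern, matching the span of the test readout
    n_pat = len(patterns)
    windows = []
    for j in range(n_pat):
        onset = settle_ms + ((presentations - 1) * n_pat + j) * schedule.theta_ms
        windows.append((onset, onset + schedule.gamma_ms))
    return network, patterns, checkpoints, record, windows


def evaluate_checkpoint(
    network: NetworkInstance,
    checkpoint: Checkpoint,
    patterns: list[PatternSpec],
    train_record: SpikeRecord,
    train_out_windows: list[tuple[float, float]],
    degradation_pct: float = 50.0,
    seed: int = 0,
    dt: float = 0.2,
    forced: bool = False,
    overlap_aware: bool | None = None,
    population: str = "members",
    mode: str = "sequential",
) -> MetricsReport:
    """Test one checkpoint against degraded cues and score the retrieval.

    Cues are presented sequentially (one per theta cycle) by default so
    that each readout window is attributable to one assembly.  Activity
    vectors span the union of all assembly members (``population =
    'members'``); ``'all_pc'`` spans the whole pyramidal population.
    """
    seeds = derive_seeds(seed)
    cue_rng = np.random.default_rng(seeds.cues)
    if overlap_aware is None:
        overlap_aware = any(a.shared_with for a in network.assemblies)
    cues: list[CueSpec] = []
    for pat, asm in zip(patterns, network.assemblies):
        cues.append(degrade_pattern(pat, degradation_pct,
                                    overlap_aware=overlap_aware,
                                    assembly=asm, rng=cue_rng))
    snr, snr_norm = m.autoassociation_snr(network, weights=checkpoint.weights)
    pct = m.fraction_at_max(network, weights=checkpoint.weights)
    result = run_test_from_checkpoint(
        network, checkpoint, cues, dt=dt, seed=seeds.test_background,
        forced=forced, merge_shared=overlap_aware, mode=mode)
    if population == "members":
        pc_ids = np.unique(np.concatenate(
            [a.member_ids for a in network.assemblies]))
    elif population == "all_pc":
        pc_ids = np.arange(network.pc_slice.start, network.pc_slice.stop)
    else:
        raise ValueError(f"unknown population {population!r}")
    accs: dict[int, float] = {}
    for pat, cue, readout, window in zip(patterns, cues,
                                         result.readout_windows,
                                         train_out_windows):
        train_in = _indicator(pat.member_ids, pc_ids)
        test_in = _indicator(cue.member_ids, pc_ids)
        train_out = m.activity_vector(train_record, window, pc_ids)
        test_out = m.activity_vector(result.record, readout, pc_ids)
        accs[pat.assembly_id] = m.reconstruction_accuracy(
            train_in, test_in, train_out, test_out)
    return MetricsReport(
        accuracy_per_assembly=accs,
        accuracy_mean=float(np.mean(list(accs.values()))),
        snr=snr,
        snr_normalized_pct=snr_norm,
        pct_at_max=pct,
    )


def run_completion_experiment(
    config: NetworkConfig,
    assembly_size: int,
    n_assemblies: int = 3,
    overlap_fraction: float = 0.0,
    presentations: int = 30,
    checkpoint_every: int = 5,
    degradations: tuple[float, ...] = (50.0,),
    seed: int = 0,
    test_checkpoints: str = "first_last",
    settle_ms: float = 1000.0,
    dt: float = 0.2,
    forced: bool = False,
) -> ExperimentResult:
    """Full pipeline: build, train, downscale, test, quantify.

    ``test_checkpoints`` selects which checkpoints to score: 'first_last'
    (the untrained state and the final checkpoint), 'last', or 'all'.
    """
    network, patterns, checkpoints, record, windows = train_assemblies(
        config, assembly_size, n_assemblies, overlap_fraction,
        presentations, checkpoint_every, seed, settle_ms, dt=dt, forced=forced)
    result = ExperimentResult(network=network, patterns=patterns,
                              checkpoints=checkpoints, train_record=record,
                              train_out_windows=windows)
    if test_checkpoints == "all":
        to_test = [initial_checkpoint(network)] + checkpoints
    elif test_checkpoints == "first_last":
        to_test = [initial_checkpoint(network), checkpoints[-1]]
    elif test_checkpoints == "last":
        to_test = [checkpoints[-1]]
    else:
        raise ValueError(f"unknown test_checkpoints mode {test_checkpoints!r}")
    for ckpt in to_test:
        for d in degradations:
            report = evaluate_checkpoint(
                network, ckpt, patterns, record, windows,
                degradation_pct=d, seed=seed, dt=dt, forced=forced)
            result.tests.append(TestOutcome(presentations=ckpt.presentations,
                                            degradation_pct=d, report=report))
    return result
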