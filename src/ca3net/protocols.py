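"""Training and testing protocols for cell-assembly formation and recall.

Training follows a theta-nested-gamma stimulation scheme: each input
pattern commands a frozen, randomized train of (by default) 4 spikes per
assembly member inside a 20 ms gamma window, one pattern per 200 ms theta
cycle, patterns presented round-robin.  Testing presents degraded cues —
a randomly chosen subset of assembly members replaying their training
spike times — and the network is read out over the cue's gamma window,
within which the strengthened recurrent synapses recruit the remaining
members.

Background drive is a per-neuron current drawn from the neuron type's
lognormal law (ln I ~ Normal(mu, sigma2)) and redrawn every gamma cycle
(20 ms), emulating upstream input volleys fluctuating at gamma timescale;
pyramidal cells switch to a presentation-specific draw inside pattern
windows.

Between training and testing, plastic weights are divisively downscaled so
their mean returns to the initial weight; testing runs with plasticity
frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics_engine import Drive, Simulator, SpikeRecord
from .network_builder import (
    PC_TYPE,
    AssemblySpec,
    NetworkInstance,
    NeuronTypeSpec,
    round_half_up,
)
from .plasticity import downscale_weights

__all__ = [
    "PatternSpec",
    "CueSpec",
    "ScheduleEntry",
    "StimulusSchedule",
    "Checkpoint",
    "ScheduleConflictError",
    "DegenerateCueError",
    "CheckpointError",
    "generate_pattern",
    "build_training_schedule",
    "degrade_pattern",
    "build_testing_schedule",
    "sample_background_currents",
    "network_background",
    "compile_drive",
    "initial_checkpoint",
    "run_training",
    "run_test_from_checkpoint",
    "TestResult",
]

THETA_MS = 200.0
GAMMA_MS = 20.0
DEFAULT_SPIKES_PER_PATTERN = 4
#: 2 ms suprathreshold pulse; amplitude chosen so a resting pyramidal cell
#: fires within the pulse (and keeps doing so after earlier spikes in the
#: same gamma window have raised its recovery variable)
PULSE_AMPLITUDE_PA = 4000.0
PULSE_DURATION_MS = 2.0


class ScheduleConflictError(ValueError):
    pass


class DegenerateCueError(ValueError):
    pass


class CheckpointError(ValueError):
    pass


@dataclass
class PatternSpec:
    """A frozen input pattern: per-member spike offsets inside a gamma window."""

    assembly_id: int
    member_ids: np.ndarray            # global PC indices
    offsets: np.ndarray               # (n_members, n_spikes) ms within [0, window)
    window_ms: float = GAMMA_MS

    @property
    def n_members(self) -> int:
        return int(self.member_ids.size)

    @property
    def n_spikes(self) -> int:
        return 0 if self.offsets.size == 0 else int(self.offsets.shape[1])


@dataclass
class CueSpec:
    """A degraded version of a pattern: a member subset with its spike times."""

    source: PatternSpec
    degradation_pct: float
    member_ids: np.ndarray
    offsets: np.ndarray

    @property
    def assembly_id(self) -> int:
        return self.source.assembly_id


@dataclass
class ScheduleEntry:
    onset_ms: float
    stimulus: PatternSpec | CueSpec


@dataclass
class StimulusSchedule:
    entries: list[ScheduleEntry]
    duration_ms: float
    theta_ms: float = THETA_MS
    gamma_ms: float = GAMMA_MS
    readout_windows: list[tuple[float, float]] = field(default_factory=list)

    def pattern_windows(self) -> np.ndarray:
        """(onset, offset) of every stimulus window, ms."""
        return np.array([(e.onset_ms, e.onset_ms + self.gamma_ms)
                         for e in self.entries]).reshape(-1, 2)


@dataclass
class Checkpoint:
    """Synaptic weight snapshot (pre-downscaling) after a block of training."""

    presentations: int
    weights: np.ndarray
    config_hash: str
    seed: int | None = None
    sim_state: dict | None = None     # full engine state, for exact resume


# ---------------------------------------------------------------------------
# Pattern and schedule construction
# ---------------------------------------------------------------------------

def generate_pattern(
    assembly: AssemblySpec,
    n_spikes: int = DEFAULT_SPIKES_PER_PATTERN,
    window_ms: float = GAMMA_MS,
    rng: np.random.Generator | int | None = None,
    dt: float = 0.2,
) -> PatternSpec:
    """Draw a frozen spike-time pattern for one assembly.

    Each member receives ``n_spikes`` offsets uniform in [0, window_ms),
    snapped to the integration grid.  The same PatternSpec is reused for
    every presentation.
    """
    rng = np.random.default_rng(rng)
    n = assembly.size
    if n == 0:
        raise ValueError("assembly has no members")
    if n_spikes == 0:
        offsets = np.empty((n, 0))
    else:
        offsets = rng.uniform(0.0, window_ms, size=(n, n_spikes))
        offsets = np.sort(np.floor(offsets / dt) * dt, axis=1)
    return PatternSpec(assembly_id=assembly.assembly_id,
                       member_ids=assembly.member_ids.copy(),
                       offsets=offsets, window_ms=window_ms)


def build_training_schedule(
    patterns: list[PatternSpec],
    n_presentations: int,
    theta_ms: float = THETA_MS,
    gamma_ms: float = GAMMA_MS,
    settle_ms: float = 1000.0,
) -> StimulusSchedule:
    """Round-robin theta-gamma presentation schedule.

    Pattern j of presentation p starts at
    ``settle + (p * n_patterns + j) * theta`` and occupies the first gamma
    window of its theta cycle.
    """
    if not patterns:
        raise ValueError("at least one pattern is required")
    entries = []
    for p in range(n_presentations):
        for j, pat in enumerate(patterns):
            onset = settle_ms + (p * len(patterns) + j) * theta_ms
            entries.append(ScheduleEntry(onset_ms=onset, stimulus=pat))
    duration = settle_ms + n_presentations * len(patterns) * theta_ms
    return StimulusSchedule(entries=entries, duration_ms=duration,
                            theta_ms=theta_ms, gamma_ms=gamma_ms)


def degrade_pattern(
    pattern: PatternSpec,
    degradation_pct: float,
    overlap_aware: bool = False,
    assembly: AssemblySpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> CueSpec:
    """Select the cue subset for a degraded presentation of ``pattern``.

    The cue keeps ``round_half_up((1 - d/100) * size)`` members.  With
    ``overlap_aware`` the shared and unique members of the assembly are
    sampled in the same proportion as they occur in the full assembly
    (e.g. a 300-cell assembly with 30 shared cells cued at 50% degradation
    activates 135 unique + 15 shared members).
    """
    if not (0 <= degradation_pct < 100):
        raise ValueError(f"degradation must be in [0, 100), got {degradation_pct}")
    rng = np.random.default_rng(rng)
    size = pattern.n_members
    n_cue = round_half_up((1.0 - degradation_pct / 100.0) * size)
    if n_cue == 0:
        raise DegenerateCueError(
            f"degradation {degradation_pct}% of a {size}-cell pattern leaves no cue")
    if overlap_aware:
        if assembly is None:
            raise ValueError("overlap-aware selection requires the assembly")
        shared = assembly.shared_ids
        unique = assembly.unique_ids
        n_shared_sel = round_half_up(n_cue * shared.size / size)
        n_unique_sel = n_cue - n_shared_sel
        sel = np.concatenate([
            rng.choice(shared, size=n_shared_sel, replace=False),
            rng.choice(unique, size=n_unique_sel, replace=False),
        ])
    else:
        sel = rng.choice(pattern.member_ids, size=n_cue, replace=False)
    sel = np.sort(sel)
    rows = np.searchsorted(pattern.member_ids, sel)
    return CueSpec(source=pattern, degradation_pct=degradation_pct,
                   member_ids=sel, offsets=pattern.offsets[rows])


def build_testing_schedule(
    cues: list[CueSpec],
    onset_ms: float = 500.0,
    mode: str = "simultaneous",
    duration_ms: float = 1000.0,
    theta_ms: float = THETA_MS,
    gamma_ms: float = GAMMA_MS,
    merge_shared: bool = False,
    readout_offset_ms: float = 0.0,
    readout_span_ms: float | None = None,
) -> StimulusSchedule:
    """Place degraded cues in a test run and record the readout windows.

    Simultaneous mode stimulates all cues in the same gamma window (the
    circuit must disambiguate them through its recurrent weights);
    sequential mode gives each cue its own theta cycle.  The readout
    window of a cue is the cue's own gamma window: with 1 ms recurrent
    delays the strengthened recurrent synapses recruit the non-cued
    members within a few milliseconds of the first cue spikes, so the
    cue response and the completed remainder are read out together
    (``readout_offset_ms``/``readout_span_ms`` select other
    conventions).  A neuron cued by two overlapping windows raises
    :class:`ScheduleConflictError` unless ``merge_shared`` is set.
    """
    if mode not in ("simultaneous", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    entries, readouts = [], []
    for idx, cue in enumerate(cues):
        onset = onset_ms if mode == "simultaneous" else onset_ms + idx * theta_ms
        if onset >= duration_ms:
            raise ValueError("cue onset beyond test duration")
        entries.append(ScheduleEntry(onset_ms=onset, stimulus=cue))
        span = gamma_ms if readout_span_ms is None else readout_span_ms
        readouts.append((onset + readout_offset_ms,
                         onset + readout_offset_ms + span))
    if mode == "simultaneous" and len(cues) > 1 and not merge_shared:
        seen: dict[int, int] = {}
        for idx, cue in enumerate(cues):
            for nid in cue.member_ids:
                if nid in seen:
                    raise ScheduleConflictError(
                        f"neuron {nid} cued by assemblies {seen[nid]} and "
                        f"{cue.assembly_id} in the same window")
                seen[int(nid)] = cue.assembly_id
    return StimulusSchedule(entries=entries, duration_ms=duration_ms,
                            theta_ms=theta_ms, gamma_ms=gamma_ms,
                            readout_windows=readouts)


# ---------------------------------------------------------------------------
# Background currents
# ---------------------------------------------------------------------------

def sample_background_currents(
    type_spec: NeuronTypeSpec,
    n: int,
    presentation_window: bool = False,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw per-neuron lognormal background currents for one type.

    (mu, sigma2) parameterize the underlying normal of ln(I).  With
    ``presentation_window`` the type's presentation override (if any)
    replaces the baseline parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    bg = type_spec.background
    mu, s2 = bg.mu, bg.sigma2
    if presentation_window and bg.has_presentation_override:
        mu = bg.mu_presentation if bg.mu_presentation is not None else mu
        s2 = bg.sigma2_presentation if bg.sigma2_presentation is not None else s2
    return rng.lognormal(mean=mu, sigma=float(np.sqrt(s2)), size=n)


def network_background(
    network: NetworkInstance,
    rng: np.random.Generator | int | None = None,
    n_draws: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and presentation background-current draws.

    Returns (n_draws, n_neurons) stacks (squeezed to vectors when
    ``n_draws`` is 1).  The presentation stack differs from the baseline
    only for types carrying a presentation override (pyramidal cells).
    Successive draws realize the fluctuation of upstream drive over time;
    the engine switches draws at caller-chosen boundaries.
    """
    rng = np.random.default_rng(rng)
    n = network.n_neurons
    base = np.zeros((n_draws, n))
    pres = np.zeros((n_draws, n))
    for name, spec in network.config.neuron_types.items():
        lo = network.type_offsets[name]
        hi = lo + spec.count
        for k in range(n_draws):
            base[k, lo:hi] = sample_background_currents(spec, spec.count, False, rng)
            if spec.background.has_presentation_override:
                pres[k, lo:hi] = sample_background_currents(spec, spec.count, True, rng)
            else:
                pres[k, lo:hi] = base[k, lo:hi]
    if n_draws == 1:
        return base[0], pres[0]
    return base, pres


def background_redraw_starts(duration_ms: float, redraw_ms: float,
                             dt: float = 0.2) -> np.ndarray:
    """Step indices at which the background draw switches (first covers 0)."""
    times = np.arange(0.0, duration_ms, redraw_ms)
    return np.round(times / dt).astype(np.int64)


# ---------------------------------------------------------------------------
# Drive compilation and phase runners
# ---------------------------------------------------------------------------

def compile_drive(
    schedule: StimulusSchedule,
    dt: float = 0.2,
    forced: bool = False,
    pulse_amplitude: float = PULSE_AMPLITUDE_PA,
    pulse_duration_ms: float = PULSE_DURATION_MS,
) -> Drive:
    """Turn a schedule into the engine's step-indexed drive arrays.

    In pulse mode a current pulse starts at each commanded spike time; in
    forced mode the neuron is made to spike exactly at the commanded time
    (spike emission lands on the grid point of that time).
    """
    steps, neurons = [], []
    for entry in schedule.entries:
        stim = entry.stimulus
        if stim.offsets.size == 0:
            continue
        times = entry.onset_ms + stim.offsets              # (n_members, n_spikes)
        grid = np.round(times / dt).astype(np.int64)
        if forced:
            grid = np.maximum(grid - 1, 0)  # spike emission = (step + 1) dt
        ids = np.repeat(stim.member_ids, stim.offsets.shape[1])
        steps.append(grid.ravel())
        neurons.append(ids)
    if steps:
        steps_arr = np.concatenate(steps)
        neurons_arr = np.concatenate(neurons)
        order = np.argsort(steps_arr, kind="stable")
        steps_arr, neurons_arr = steps_arr[order], neurons_arr[order]
    else:
        steps_arr = np.empty(0, np.int64)
        neurons_arr = np.empty(0, np.int64)
    windows = np.round(schedule.pattern_windows() / dt).astype(np.int64)
    windows = windows[np.argsort(windows[:, 0])] if windows.size else windows
    return Drive(pulse_steps=steps_arr, pulse_neurons=neurons_arr,
                 pulse_amplitude=pulse_amplitude,
                 pulse_duration_ms=pulse_duration_ms,
                 forced=forced, presentation_windows=windows)


def initial_checkpoint(network: NetworkInstance) -> Checkpoint:
    """Checkpoint of the untrained state: 0 presentations, all plastic
    weights at w_init (regardless of any training the network instance has
    since undergone)."""
    return Checkpoint(presentations=0,
                      weights=np.full_like(network.plastic_weights,
                                           network.config.w_init),
                      config_hash=network.config.content_hash(),
                      seed=network.seed)


def run_training(
    network: NetworkInstance,
    schedule: StimulusSchedule,
    checkpoint_every: int = 5,
    dt: float = 0.2,
    seed: int | None = None,
    forced: bool = False,
    pulse_amplitude: float = PULSE_AMPLITUDE_PA,
    keep_sim_state: bool = False,
    resume_from: Checkpoint | None = None,
    return_record: bool = False,
    background_redraw_ms: float = GAMMA_MS,
    plasticity_windows_only: bool = True,
):
    """Simulate the training phase with plasticity on; checkpoint weights.

    By default STDP is gated to the presentation windows (the spikes a
    pattern elicits, plus whatever background activity coincides with
    them), emulating encoding-phase neuromodulatory gating of hippocampal
    plasticity; ``plasticity_windows_only=False`` restores continuous
    plasticity.  A checkpoint is stored after every ``checkpoint_every``
    presentations-per-pattern (e.g. 65 presentations at interval 5 yield 13
    checkpoints).  The network's plastic weights are mutated in place; the
    checkpoints hold copies.  With ``resume_from`` (a checkpoint carrying
    ``sim_state``) training continues mid-run and reproduces the
    uninterrupted run exactly.
    """
    n_patterns = len({id(e.stimulus) for e in schedule.entries})
    n_presentations = len(schedule.entries) // max(n_patterns, 1)
    settle_ms = schedule.entries[0].onset_ms if schedule.entries else 0.0
    drive = compile_drive(schedule, dt=dt, forced=forced,
                          pulse_amplitude=pulse_amplitude)
    starts = background_redraw_starts(schedule.duration_ms,
                                      background_redraw_ms, dt)
    base, pres = network_background(network, np.random.default_rng(seed),
                                    n_draws=max(starts.size, 1))
    sim = Simulator(network, dt=dt, plasticity_on=True,
                    background=base, background_presentation=pres,
                    background_starts=starts, drive=drive,
                    stdp_windows_only=plasticity_windows_only)
    start_block = 0
    if resume_from is not None:
        if resume_from.sim_state is None:
            raise CheckpointError("checkpoint has no simulator state to resume from")
        if resume_from.config_hash != network.config.content_hash():
            raise CheckpointError("checkpoint was taken under a different configuration")
        sim.set_state(resume_from.sim_state)
        network.plastic_weights[:] = resume_from.weights
        start_block = resume_from.presentations // checkpoint_every

    block_ms = checkpoint_every * n_patterns * schedule.theta_ms
    n_blocks = n_presentations // checkpoint_every
    checkpoints: list[Checkpoint] = []
    cfg_hash = network.config.content_hash()
    for blk in range(start_block, n_blocks):
        t_end = settle_ms + (blk + 1) * block_ms
        sim.run(int(round(t_end / dt)) - sim.step_index)
        presentations = (blk + 1) * checkpoint_every
        checkpoints.append(Checkpoint(
            presentations=presentations,
            weights=network.plastic_weights.copy(),
            config_hash=cfg_hash,
            seed=seed,
            sim_state=sim.get_state() if keep_sim_state else None,
        ))
    # run out any remainder of the schedule (partial blocks train but are
    # not checkpointed)
    total_steps = int(round(schedule.duration_ms / dt))
    if sim.step_index < total_steps:
        sim.run(total_steps - sim.step_index)
    if return_record:
        return checkpoints, sim.spike_record(seed=seed)
    return checkpoints


@dataclass
class TestResult:
    record: SpikeRecord
    readout_windows: list[tuple[float, float]]
    cues: list[CueSpec]
    downscale_factor: float
    schedule: StimulusSchedule


def run_test_from_checkpoint(
    network: NetworkInstance,
    checkpoint: Checkpoint,
    cues: list[CueSpec],
    duration_ms: float = 1000.0,
    onset_ms: float = 500.0,
    mode: str = "simultaneous",
    dt: float = 0.2,
    seed: int | None = None,
    forced: bool = False,
    pulse_amplitude: float = PULSE_AMPLITUDE_PA,
    merge_shared: bool = False,
    background_redraw_ms: float = GAMMA_MS,
) -> TestResult:
    """Divisively downscale a checkpoint's weights and run the test phase.

    Plasticity is frozen; the mean plastic weight during the test equals
    w_init exactly.  Returns the raster together with the readout windows
    used by the reconstruction metric.
    """
    if checkpoint.config_hash != network.config.content_hash():
        raise CheckpointError("checkpoint was taken under a different configuration")
    scaled, factor = downscale_weights(checkpoint.weights, network.config.w_init)
    network.plastic_weights[:] = scaled
    schedule = build_testing_schedule(cues, onset_ms=onset_ms, mode=mode,
                                      duration_ms=duration_ms,
                                      merge_shared=merge_shared)
    drive = compile_drive(schedule, dt=dt, forced=forced,
                          pulse_amplitude=pulse_amplitude)
    starts = background_redraw_starts(duration_ms, background_redraw_ms, dt)
    base, pres = network_background(network, np.random.default_rng(seed),
                                    n_draws=max(starts.size, 1))
    sim = Simulator(network, dt=dt, plasticity_on=False,
                    background=base, background_presentation=pres,
                    background_starts=starts, drive=drive)
    sim.run(int(round(duration_ms / dt)))
    return TestResult(record=sim.spike_record(seed=seed),
                      readout_windows=schedule.readout_windows,
                      cues=cues, downscale_factor=factor, schedule=schedule)
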