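"""Symmetric spike-timing-dependent plasticity and divisive downscaling.

The learning rule for pyramidal-to-pyramidal synapses is a symmetric
exponential kernel: every ordered pair of one presynaptic and one
postsynaptic spike contributes ``dw = A * exp(-|dt| / tau)`` regardless of
spike order, with ``tau = 20 ms``.  The kernel is realized online with
per-neuron exponentially decaying spike traces (all-pairs interaction), so
the accumulated change equals the explicit double sum over spike pairs;
each pair is credited exactly once, at the later of its two spikes, and
exactly coincident spikes contribute ``A`` once per synapse.

Between training and testing every plastic weight is divided by one common
factor chosen so that the mean returns to ``w_init`` — a single divisive
downscaling event in the spirit of sleep-related synaptic homeostasis. The
rescaling preserves the shape of the weight distribution and the ratio
between any two weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPRule",
    "SpikeTrace",
    "stdp_kernel",
    "apply_stdp_online",
    "accumulate_weight_change",
    "clip_weight",
    "downscale_weights",
    "simultaneous_spike_tiebreak",
    "DegenerateStateError",
]


class DegenerateStateError(ValueError):
    """Raised when downscaling is requested for a degenerate weight state."""


@dataclass(frozen=True)
class STDPRule:
    A: float
    tau: float = 20.0
    w_min: float = 0.0
    w_max: float = np.inf

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.A < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.A}")
        if not self.w_min < self.w_max:
            raise ValueError("require w_min < w_max")


def stdp_kernel(dt, rule: STDPRule):
    """Weight change for a single spike pair separated by ``dt`` ms.

    Symmetric in the sign of ``dt``, maximal (= A) at coincidence, and
    monotonically decreasing in ``|dt|``.  Accepts scalars or arrays.
    """
    return rule.A * np.exp(-np.abs(dt) / rule.tau)


@dataclass
class SpikeTrace:
    """Exponentially decaying spike trace of one neuron.

    Bumps by 1 at each of the neuron's own spikes and decays with the kernel
    time constant in between; its value at time t equals
    ``sum_s exp(-(t - t_s)/tau)`` over past spikes, which is exactly the
    quantity the all-pairs kernel needs from the other side of a synapse.
    """

    tau: float
    value: float = 0.0
    last_time: float = -np.inf

    def at(self, t: float) -> float:
        if self.value == 0.0:
            return 0.0
        return self.value * np.exp(-(t - self.last_time) / self.tau)

    def bump(self, t: float) -> None:
        self.value = self.at(t) + 1.0
        self.last_time = t


def apply_stdp_online(
    weight: float,
    pre_trace: SpikeTrace,
    post_trace: SpikeTrace,
    event: str,
    t: float,
    rule: STDPRule,
    coincident: bool = False,
) -> float:
    """Update one synaptic weight at a spike of either side.

    ``event`` names the side that just spiked ('pre' or 'post'); the update
    credits every pair formed with the *earlier* spikes of the other side
    via that side's trace.  ``coincident`` adds the single ``A`` owed when
    the other side spikes on the same time-grid point (the caller must not
    also have bumped that trace for the simultaneous spike).  The result is
    clipped to the rule's bounds.

    Traces are not bumped here: callers bump all traces for spikes at ``t``
    after every synapse touching those neurons has been updated.
    """
    if event == "pre":
        other = post_trace
    elif event == "post":
        other = pre_trace
    else:
        raise ValueError(f"event must be 'pre' or 'post', got {event!r}")
    dw = rule.A * other.at(t)
    if coincident:
        dw += simultaneous_spike_tiebreak(rule)
    return clip_weight(weight + dw, rule)


def simultaneous_spike_tiebreak(rule: STDPRule) -> float:
    """Contribution of one exactly coincident pre/post spike pair: A, once."""
    return rule.A


def accumulate_weight_change(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    rule: STDPRule,
    w0: float = 0.0,
    clip: bool = False,
) -> float:
    """Run the online trace algorithm over two complete spike trains.

    Returns the final weight starting from ``w0``.  With ``clip=False`` the
    result equals ``w0`` plus the all-pairs double sum of the kernel, which
    is how the online implementation is validated.
    """
    eff = rule if clip else STDPRule(A=rule.A, tau=rule.tau,
                                     w_min=-np.inf, w_max=np.inf)
    pre = SpikeTrace(tau=rule.tau)
    post = SpikeTrace(tau=rule.tau)
    events = sorted(
        [(float(t), "pre") for t in np.atleast_1d(pre_times)]
        + [(float(t), "post") for t in np.atleast_1d(post_times)]
    )
    w = float(w0)
    i = 0
    while i < len(events):
        t = events[i][0]
        batch = []
        while i < len(events) and events[i][0] == t:
            batch.append(events[i][1])
            i += 1
        n_pre = batch.count("pre")
        n_post = batch.count("post")
        # cross-pairs with earlier spikes, once per event in the batch
        for side in batch:
            w += (eff.A * (post if side == "pre" else pre).at(t))
        # coincident pairs within the batch: A once per (pre, post) pair
        w += n_pre * n_post * simultaneous_spike_tiebreak(eff)
        if clip:
            w = clip_weight(w, rule)
        for _ in range(n_pre):
            pre.bump(t)
        for _ in range(n_post):
            post.bump(t)
    return w


def clip_weight(w, rule: STDPRule):
    """Clamp weight(s) to [w_min, w_max]."""
    return np.clip(w, rule.w_min, rule.w_max)


def downscale_weights(weights: np.ndarray, w_init: float) -> tuple[np.ndarray, float]:
    """Divide all plastic weights by one factor so their mean equals w_init.

    Returns the rescaled vector and the scalar factor ``mean(w) / w_init``.
    Idempotent and shape-preserving.  Raises :class:`DegenerateStateError`
    if the mean weight is not positive.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.size == 0:
        raise DegenerateStateError("cannot downscale an empty weight vector")
    mean = float(weights.mean())
    if mean <= 0:
        raise DegenerateStateError(f"mean plastic weight must be positive, got {mean}")
    factor = mean / w_init
    return weights / factor, factor
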