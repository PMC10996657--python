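"""Quantification of auto-association and pattern completion.

Pattern reconstruction accuracy compares Pearson correlation coefficients
(PCCs) between binary activity vectors over the pyramidal population:

    PCC_in  = corr(training input,  testing input)
    PCC_out = corr(training output, testing output)
    accuracy = 100 * (PCC_out - PCC_in) / (1 - PCC_in)

Input vectors indicate which cells were commanded to fire; output vectors
indicate which cells actually spiked inside a 20 ms readout window.
Accuracy is 100% iff the test output correlates perfectly with the
training output, 0% when the output resembles the cue no more than the
input did, and can be negative when recall is worse than the cue.

Auto-association is summarized by the signal-to-noise ratio of plastic
weights — mean weight between members of the same assembly over mean
weight of all other pyramidal-pyramidal synapses — and by the fraction of
within-assembly synapses that have saturated at the maximum weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics_engine import SpikeRecord
from .network_builder import AssemblySpec, NetworkInstance, PC_TYPE

__all__ = [
    "ActivityVector",
    "MetricsReport",
    "MetricError",
    "activity_vector",
    "reconstruction_accuracy",
    "autoassociation_snr",
    "fraction_at_max",
    "firing_rate_summary",
    "learning_curve_inflection",
    "willshaw_capacity",
    "treves_rolls_capacity",
]


class MetricError(ValueError):
    pass


@dataclass
class ActivityVector:
    """Binary (or count) activity of a neuron set in one gamma window."""

    neuron_ids: np.ndarray
    values: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.neuron_ids.size != self.values.size:
            raise MetricError("index set and value vector differ in length")


@dataclass
class MetricsReport:
    accuracy_per_assembly: dict[int, float] = field(default_factory=dict)
    accuracy_mean: float = np.nan
    snr: float = np.nan
    snr_normalized_pct: float = np.nan
    pct_at_max: float = np.nan
    firing_rates: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy_mean": self.accuracy_mean,
            "snr": self.snr,
            "snr_normalized_pct": self.snr_normalized_pct,
            "pct_at_max": self.pct_at_max,
        }
        for k, v in self.accuracy_per_assembly.items():
            out[f"accuracy_assembly_{k}"] = v
        return out


def activity_vector(
    spikes: SpikeRecord,
    window: tuple[float, float],
    neuron_ids: np.ndarray,
    binary: bool = True,
) -> ActivityVector:
    """Spiked/silent indicator (or spike count) per neuron within [t0, t1)."""
    t0, t1 = window
    if t1 <= t0:
        raise MetricError(f"empty window [{t0}, {t1})")
    neuron_ids = np.asarray(neuron_ids)
    if neuron_ids.size == 0:
        raise MetricError("empty neuron set")
    m = (spikes.times >= t0) & (spikes.times < t1)
    counts = np.bincount(spikes.neuron_ids[m],
                         minlength=int(neuron_ids.max()) + 1)[neuron_ids]
    values = (counts > 0).astype(float) if binary else counts.astype(float)
    return ActivityVector(neuron_ids=neuron_ids, values=values, window=(t0, t1))


def _pcc(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise MetricError("correlation undefined for a constant activity vector")
    return float(np.corrcoef(x, y)[0, 1])


def reconstruction_accuracy(
    train_in: ActivityVector,
    test_in: ActivityVector,
    train_out: ActivityVector,
    test_out: ActivityVector,
) -> float:
    """Pattern-reconstruction accuracy in percent (may be negative)."""
    vecs = (train_in, test_in, train_out, test_out)
    n = {v.values.size for v in vecs}
    if len(n) != 1:
        raise MetricError("all four activity vectors must span the same neuron set")
    pcc_in = _pcc(train_in.values, test_in.values)
    if pcc_in == 1.0:
        raise MetricError("input PCC is 1 (undegraded cue): accuracy undefined")
    pcc_out = _pcc(train_out.values, test_out.values)
    return 100.0 * (pcc_out - pcc_in) / (1.0 - pcc_in)


def _within_mask(network: NetworkInstance) -> np.ndarray:
    """True for plastic synapses whose pre and post share an assembly."""
    pop = network.plastic_population
    pc0 = network.type_offsets[PC_TYPE]
    n_pre = len(pop.indptr) - 1
    pre_local = np.repeat(np.arange(n_pre), np.diff(pop.indptr))
    post_local = pop.targets - pc0
    n_pc = network.config.neuron_types[PC_TYPE].count
    member = np.zeros((len(network.assemblies), n_pc), dtype=bool)
    for i, a in enumerate(network.assemblies):
        member[i, a.member_ids - pc0] = True
    within = np.zeros(pre_local.size, dtype=bool)
    for i in range(len(network.assemblies)):
        within |= member[i, pre_local] & member[i, post_local]
    return within


def autoassociation_snr(
    network: NetworkInstance,
    weights: np.ndarray | None = None,
    downscaled_min: float | None = None,
) -> tuple[float, float]:
    """(SNR, normalized SNR in % of its ceiling) of the plastic weights.

    Signal: mean weight over synapses joining two members of the same
    assembly.  Noise: mean weight over every other plastic synapse.  The
    ceiling is reached when within-assembly synapses sit at the downscaled
    maximum weight and all others at the downscaled minimum
    (``downscaled_min`` defaults to the observed minimum non-assembly
    weight; a zero floor gives an infinite ceiling and the normalized value
    is reported against it as 0 unless the SNR itself is infinite).
    """
    w = network.plastic_weights if weights is None else np.asarray(weights)
    within = _within_mask(network)
    if not within.any() or within.all():
        raise MetricError("need both within-assembly and non-assembly plastic synapses")
    signal = float(w[within].mean())
    noise = float(w[~within].mean())
    if noise == 0.0:
        return np.inf, 100.0
    ratio = signal / noise
    from .plasticity import downscale_weights

    w_max = network.plasticity.w_max
    hypothetical = np.where(within, w_max, w[~within].min()
                            if downscaled_min is None else downscaled_min)
    scaled, _ = downscale_weights(hypothetical, network.config.w_init)
    sig_max = scaled[within].mean()
    noise_max = scaled[~within].mean()
    if noise_max == 0.0:
        return ratio, (100.0 if np.isinf(ratio) else 0.0)
    ratio_max = sig_max / noise_max
    return ratio, 100.0 * ratio / ratio_max


def fraction_at_max(
    network: NetworkInstance,
    weights: np.ndarray | None = None,
    w_max: float | None = None,
    eps: float | None = None,
) -> float:
    """% of within-assembly plastic synapses at the maximum weight.

    Evaluated on pre-downscaling weights; ``eps`` defaults to 1e-6 * w_max.
    """
    w = network.plastic_weights if weights is None else np.asarray(weights)
    if w_max is None:
        w_max = network.plasticity.w_max
    if eps is None:
        eps = 1e-6 * w_max
    if eps < 0:
        raise MetricError("eps must be non-negative")
    within = _within_mask(network)
    n_within = int(within.sum())
    if n_within == 0:
        raise MetricError("no within-assembly plastic synapses")
    return 100.0 * float((w[within] >= w_max - eps).sum()) / n_within


def firing_rate_summary(
    spikes: SpikeRecord,
    network: NetworkInstance,
    duration_ms: float | None = None,
    exclude_windows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean +/- sd firing rate (Hz) per neuron type.

    ``exclude_windows`` ((n, 2) ms intervals) removes stimulus periods from
    both the spike counts and the effective duration.
    """
    if duration_ms is None:
        duration_ms = spikes.duration
    if duration_ms <= 0:
        raise MetricError("duration must be positive")
    times, ids = spikes.times, spikes.neuron_ids
    effective = duration_ms
    if exclude_windows is not None and len(exclude_windows):
        keep = np.ones(times.size, dtype=bool)
        for t0, t1 in exclude_windows:
            keep &= ~((times >= t0) & (times < t1))
            effective -= (t1 - t0)
        times, ids = times[keep], ids[keep]
    counts = np.bincount(ids, minlength=network.n_neurons)
    rates = counts / (effective / 1000.0)
    names = network.config.type_names
    rows = []
    for name in names:
        lo = network.type_offsets[name]
        hi = lo + network.config.neuron_types[name].count
        r = rates[lo:hi]
        rows.append({"type": name, "mean_hz": float(r.mean()),
                     "sd_hz": float(r.std()), "n": hi - lo})
    return pd.DataFrame(rows)


def learning_curve_inflection(
    presentations: np.ndarray,
    accuracy: np.ndarray,
) -> tuple[float, bool]:
    """Abscissa of the steepest acceleration of the learning curve.

    Maximizes the discrete second difference
    ``a[i] - 2 a[i-1] + a[i-2]`` (uniform spacing required) and attributes
    the acceleration to checkpoint ``x[i]`` — the checkpoint at which the
    accelerated gain has materialized, so a single jump in the series maps
    to the jump's own checkpoint.  Ties break toward fewer presentations;
    the second return element flags a tie (e.g. an exactly linear series).
    """
    presentations = np.asarray(presentations, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if presentations.size < 4:
        raise MetricError("need at least 4 checkpoints for an inflection estimate")
    gaps = np.diff(presentations)
    if not np.allclose(gaps, gaps[0]):
        raise MetricError("checkpoints must be uniformly spaced")
    second = accuracy[2:] - 2 * accuracy[1:-1] + accuracy[:-2]
    best = int(np.argmax(second))            # first index wins ties
    tie = bool(np.isclose(second, second[best]).sum() > 1)
    return float(presentations[2 + best]), tie


def willshaw_capacity(c: float, gamma: float) -> float:
    """Willshaw pattern capacity P = c / gamma**2.

    ``c`` is the pyramidal-pyramidal connection probability and ``gamma``
    the sparseness ratio (assembly size / number of pyramidal cells);
    ``gamma = 1`` is the degenerate one-pattern limit P = c.
    """
    if not (0 < gamma <= 1):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if not (0 < c <= 1):
        raise ValueError(f"connection probability must be in (0, 1], got {c}")
    return c / gamma**2


def treves_rolls_capacity(c_rc: float, gamma: float, k: float = 0.2) -> float:
    """Treves-Rolls capacity estimate, P = C_RC * k / (gamma * ln(1/gamma)).

    C_RC is the number of recurrent-collateral inputs per pyramidal cell
    and k a scaling factor for the information retrievable per synapse.
    The published rendering of this formula is typographically ambiguous;
    the reading implemented here is the standard one from the
    autoassociative-memory literature.  It is provided for exploration and
    carries no validation weight.
    """
    if not (0 < gamma < 1):
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    return c_rc * k / (gamma * np.log(1.0 / gamma))
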