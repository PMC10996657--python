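# Model and methods

`ca3net` simulates cell-assembly formation and retrieval in a spiking
network patterned on mouse hippocampal area CA3: one excitatory
(pyramidal) and seven inhibitory neuron types, 51 directional connection
types, symmetric spike-timing-dependent plasticity (STDP) on the
recurrent pyramidal synapses, a theta-nested-gamma training/testing
protocol, and correlation-based quantification of pattern completion.
This note records the model equations, the parameters that matter, the
choices made where the design was genuinely open, and what the shipped
reduced-scale experiments do and do not demonstrate.

## Neurons

Each neuron is a 9-parameter Izhikevich quadratic two-variable model:

    C dv/dt = k (v − vr)(v − vt) − u + I
      du/dt = a (b (v − vr) − u),       v ≥ vpeak → v ← vmin, u ← u + d

with per-type constants (capacitance `C` in pF, potentials in mV,
currents in pA) taken from published fits for the eight CA3 types. Note
that several types have recovery couplings `b` far from zero: the
pyramidal cell's `b = −35.78` is an *amplifying* slow current that lowers
its steady-state rheobase to ≈ 98 pA (far below the ≈ 590 pA quadratic
barrier), while e.g. the MFA-ORDEN cell's `b = +12.9` raises it. The test
suite therefore validates integration against a numerically computed
steady-state rheobase rather than the quadratic barrier alone.

Integration is classical fixed-step RK4 at `dt = 0.2 ms`, with all
currents held constant across a step (piecewise-constant forcing). Spike
detection runs after the full step; spike times are recorded at the end
of the step that crossed threshold. Sub-threshold trajectories at this
step size agree with a 20×-finer reference to < 1e−4 mV over 100 ms, and
first-spike latencies to < 0.2 ms.

## Synapses

Each directional connection type carries 5-parameter Tsodyks–Markram
short-term plasticity. On arrival of a presynaptic spike (1 ms after
emission, uniformly):

    u⁺ = u + U (1 − u);  Δg = w · g · u⁺ · x;  x ← x (1 − u⁺);  u ← u⁺

with exact exponential relaxation between events (`g` decays with τ_d,
`x` recovers with τ_r, `u` decays with τ_f). Because `u` and `x` depend
only on presynaptic history, they are stored once per presynaptic cell
and connection type; per-type conductance accumulators per postsynaptic
cell make the event cost independent of the synapse count.

The conductance-to-current closure is conductance-based:
`I = Σ g_class (E_class − v)` with `E_exc = 0 mV`, `E_inh = −70 mV`
(configurable; the source publications do not state the reversal
potentials or current/conductance mode). A single receptor class per
synapse is the default; an optional slow NMDA-type component at the
recurrent pyramidal synapses (`synapses.nmda_fraction`, decay
`synapses.nmda_tau = 150 ms`) is available but off by default.

## Long-term plasticity

Recurrent pyramidal→pyramidal synapses follow a symmetric STDP rule:
every pre/post spike pair contributes `Δw = A·exp(−|Δt|/τ)` with
`τ = 20 ms`, potentiation regardless of order. The rule is realized
online with per-neuron exponentially decaying traces (all-pairs
interaction); each pair is credited once, at the later spike, and exact
coincidences contribute `A` once per synapse. The online implementation
equals the explicit double sum over spike pairs to < 1e−10 relative
error, which the test suite verifies on 1,000 random train pairs.

The weight ceiling scales inversely with assembly size,
`w*max = 6000 / size` (anchored at `w*max = 20` for 300-cell assemblies),
and the amplitude `A = (w*max − w*init)/400` lets a synapse reach the
ceiling from `w*init = 0.625` under 100 presentations of 4 exactly
coincident spikes. Weights are clipped to `[0, w*max]`.

Between training and testing every plastic weight is divided by the one
factor that returns the mean to `w*init` (divisive downscaling, in the
spirit of sleep-related synaptic homeostasis): exactly mean-restoring,
idempotent, and shape-preserving.

## Protocol

Training presents each input pattern once per 200 ms theta cycle
(round-robin over patterns), each presentation being a frozen, randomized
train of 4 spikes per assembly member inside the first 20 ms gamma window
of the cycle, delivered as 2 ms / 4,000 pA current pulses (amplitude
verified to elicit one spike per pulse at pyramidal parameters; a
hard-forcing mode exists for unit testing). A 1 s settling prefix
precedes the first presentation. Checkpoints of the plastic weight vector
are stored every 5 presentations-per-pattern.

Background drive is a per-neuron current drawn from the type's lognormal
law — `(μ, σ²)` are read as the parameters of the underlying normal of
`ln I`, the only reading that yields plausible picoampere scales — and
redrawn every 20 ms, emulating upstream input volleys fluctuating at
gamma timescale. Pyramidal cells use their presentation override
(σ² 1.5 → 1.0) inside pattern windows. A single per-phase draw is
available (`background_redraw_ms`), but see *Reduced-scale adaptations*.

Testing loads a checkpoint, downscales, freezes plasticity, and presents
degraded cues: a cue keeps `round_half_up((1 − d/100)·size)` members
(138 of 275 at 50% degradation) replaying their training spike times.
With overlapping assemblies, shared and unique members are sampled in
proportion to their prevalence (135 unique + 15 shared for a 300-cell
assembly at 50%). The experiment layer presents cues sequentially, one
per theta cycle, and reads out each assembly in its cue's own gamma
window; with 1 ms recurrent delays, recruitment of the non-cued members
completes within that window.

## Quantification

Auto-association SNR is the mean plastic weight between same-assembly
members divided by the mean over all other plastic synapses; the
normalized variant divides by the ceiling obtained if within-assembly
synapses sat at the downscaled maximum and the rest at the downscaled
observed minimum (the floor is 0 in the limit, in which case the ceiling
is infinite and the normalized value is reported accordingly). Saturation
is the percentage of within-assembly synapses within `1e−6·w*max` of the
ceiling, measured pre-downscaling.

Pattern reconstruction accuracy compares Pearson correlations of binary
activity vectors: `100·(PCC_out − PCC_in)/(1 − PCC_in)`, where the input
PCC correlates the commanded training pattern with the commanded cue and
the output PCC correlates observed training-window activity with observed
test-readout activity. Vectors span the union of all assembly members by
default. The all-pyramidal span is available, but at realistic background
rates it makes the metric structurally negative — the hundreds of
background-active cells per 20 ms window swamp the assembly-sized signal
in the output correlation while the input correlation is computed on
noise-free indicators — so it cannot be the reading that produced the
published positive accuracy curves.

The learning-curve inflection maximizes the discrete second difference of
accuracy over uniformly spaced checkpoints, attributing the acceleration
over `[x_{i−2}, x_i]` to checkpoint `x_i` (so a single jump maps to the
jump's checkpoint); ties break toward fewer presentations. Willshaw
capacity is `P = c/γ²`. A Treves–Rolls-style estimate
`P = C_RC·k/(γ·ln(1/γ))` is provided for exploration only; the published
rendering of that formula is typographically ambiguous and the
implementation documents its chosen reading.

## Network construction and scaling

Wiring is Bernoulli per ordered neuron pair at type-pair-specific
probability, autapses excluded, at most one synapse per ordered pair,
1 ms delays everywhere. Pairwise assembly overlaps are mutually disjoint
(no cell in three assemblies), with `round_half_up(f·size)` shared cells
per pair.

The shipped full-scale configuration carries the published neuron and
synapse parameters; the population counts (except the published
Axo-Axonic count) and the 51 connection probabilities are synthetic
stand-ins chosen for internal consistency, as the published values exist
only in a circuit diagram. They are labelled as such in the file and no
quantitative claim rests on them.

`scale_network` shrinks a configuration while preserving expected
in-degrees: counts × factor, probabilities × 1/factor capped at 1 (with
warnings when the cap binds, since in-degrees are then no longer
preserved). The desk-scale configuration is the full-scale circuit at
factor 0.04 (2,975 pyramidal cells, 386 interneurons).

### Reduced-scale adaptations

Three adaptations make the desk-scale analog both stable and functional;
all are documented here because they are the package's own engineering of
the scaled-down substitute, not properties of the full-scale model:

1. **Weight budget × √factor.** Probability inflation at unchanged
   absolute assembly size multiplies the number of within-assembly
   synapses per member by 1/factor. Keeping the full-scale budget makes
   the saturated convergent drive 1/factor too strong (epileptic);
   scaling it by the full factor preserves mean drive but smears away the
   strong unitary synapses that sparse-connectivity completion relies on
   (no recruitment). The geometric mean preserves both behaviours; at
   factor 0.04 the desk budget is 1200 (`w*max = 24` for 50-cell
   assemblies).

2. **Gamma-timescale background redraw.** With one draw per phase, the
   heavy lognormal tail (σ² = 1.5) leaves ~2.6% of pyramidal cells
   suprathreshold for the entire phase; these tonic cells saturate each
   other's plastic synapses within a second. Redrawing every 20 ms keeps
   the marginal distribution exactly as specified while bounding how long
   any cell stays suprathreshold.

3. **Encoding-gated plasticity.** Even with fast redraw, continuous STDP
   at desk scale is unstable at any weight budget that also supports
   completion, because probability caps bound the achievable inhibitory
   in-degree at ~1/10 of full scale. Training therefore applies STDP only
   to spikes emitted inside presentation windows — an encoding-phase
   gating in the spirit of theta-state neuromodulatory gating of
   hippocampal plasticity. Continuous plasticity remains available
   (`plasticity_windows_only=False`).

With these defaults, the shipped reduced-scale experiment (2,975 PCs,
3 assemblies of 50, 30 presentations, 50% degradation, seed 1) trains in
about a minute on one CPU: non-assembly weights stay at `w*init` within
2%, the auto-association SNR reaches ≈ 33, ≈ 40% of assembly synapses
saturate, and reconstruction accuracy rises from ≈ −5% (untrained) to
≈ 70% (trained); across seeds 1–7 trained accuracy spans ≈ 62–81%.

## What the reduced-scale experiments do and do not show

They demonstrate the mechanism end to end — Hebbian assembly formation
under a theta-gamma code, homeostatic renormalization, and recurrent
pattern completion from half cues, quantified exactly as defined above —
with every parameter that the source model publishes in tables used
verbatim. They do not reproduce the full-scale quantitative results: the
published headline numbers come from an 84,053-neuron network with
~176 M synapses trained for 70 s on GPU hardware, with connection
probabilities and counts this package only carries as synthetic
stand-ins. In particular the published full-scale firing-rate table and
the reconstruction accuracy of 1.68% at 97.5% degradation (assembly size
275) are recorded as full-scale targets that a desk run cannot check;
the desk analog's background rates are several-fold higher than the
full-scale table because capped probabilities cannot reproduce full-scale
inhibitory convergence.

## Numerical and degenerate-input conventions

- `round_half_up` everywhere a fractional cell count becomes an integer.
- Reconstruction accuracy raises on undegraded cues (input PCC = 1) and
  on constant activity vectors rather than returning NaN.
- Downscaling raises on empty or non-positive-mean weight vectors.
- Zero-variance background laws degenerate to the constant `e^μ`.
- Weight updates apply immediately at each spike event; clipping after
  each event. With `A = 0`, training leaves weights bit-identical.
- All randomness flows from explicit seeds, split by role (wiring,
  patterns, training background, cue selection, test background);
  identical seeds give bit-identical spike records, checkpoints and
  metrics. Checkpoints carry the full dynamic state, so interrupted and
  resumed training reproduces the uninterrupted run exactly.

## Known limitations

- Uniform 1 ms delays, point neurons, no spatial geometry.
- One Bernoulli trial per ordered pair: no multiple contacts.
- No inhibitory plasticity; no replay/sharp-wave phase beyond the single
  downscaling event.
- The desk-scale analog's absolute firing rates and its three scaling
  adaptations (above) are engineering choices of the reduced model, not
  measurements of the full-scale system.
- The Treves–Rolls capacity reading is a documented interpretation.
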