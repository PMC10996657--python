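# ca3net

Cell-assembly formation and retrieval in a spiking network model of mouse
hippocampal area CA3.

Area CA3 is the classic substrate for auto-associative memory: groups of
pyramidal cells (PCs) that strengthen their mutual recurrent synapses
during an experience — cell assemblies — can later be reactivated in full
from a partial cue (pattern completion). `ca3net` is a
simulation-and-analysis pipeline for studying this process in a circuit
with realistic cellular diversity: 8 neuron types (PCs plus 7 interneuron
classes) as 9-parameter Izhikevich models, 51 directional connection
types with 5-parameter Tsodyks–Markram short-term plasticity, Bernoulli
wiring, lognormal background drive, and a symmetric STDP rule
Δw = A·e^(−|Δt|/τ) (τ = 20 ms) on the recurrent PC→PC synapses.

The model's long-term plasticity constants follow an inverse-proportional
rule: the maximum synaptic weight for assemblies of `n` cells is
w*max = 6000/n (so a 300-cell assembly has w*max = 20), and the
potentiation amplitude A = (w*max − 0.625)/400 lets a synapse climb from
the initial weight 0.625 to its ceiling under 100 presentations of
4-spike training patterns. Training interleaves patterns in a
theta-nested-gamma code (one 20 ms pattern per 200 ms theta cycle);
between training and testing all plastic weights are divisively
downscaled so their mean returns to 0.625; retrieval from degraded cues
is quantified by the pattern-reconstruction accuracy
100·(PCC_out − PCC_in)/(1 − PCC_in) built from Pearson correlations of
binary activity vectors, alongside the auto-association signal-to-noise
ratio (mean within-assembly weight / mean elsewhere).

The package targets desk-scale experimentation: a scaled-down circuit
(~3,000 PCs) that preserves expected in-degrees runs a full
train–downscale–test experiment in about a minute on one CPU. See
`docs/methods.md` for the model equations, parameter provenance, and the
scaling adaptations (and their limits) in detail.

## Worked example

Reproduce the assembly-size-dependent plasticity constants table:

```
$ ca3net reproduce-table4
size	g_max	w_max	A
50	66.00	120	0.298
75	44.00	80	0.198
...
275	12.00	21.82	0.053
300	11.00	20	0.048
...
600	5.50	10	0.023
```

`w_max` is the per-synapse weight ceiling, `A` the STDP amplitude, and
`g_max = w_max · g` the maximum effective conductance (nS) given the
unitary PC→PC conductance g = 0.55 nS.

Run a desk-scale assembly-formation experiment from Python:

```python
from ca3net import load_config, builtin_config_path, run_completion_experiment

cfg = load_config(builtin_config_path("desk_scale"))
res = run_completion_experiment(
    cfg, assembly_size=50, n_assemblies=3, presentations=30,
    checkpoint_every=5, degradations=(50.0,), seed=1,
    test_checkpoints="first_last")
print(res.learning_table())
```

prints (seed 1):

```
   presentations  degradation_pct  accuracy_mean        snr  pct_at_max
0              0             50.0      -4.549497   1.000000    0.000000
1             30             50.0      69.976482  32.724513   41.491737
```

Before training, a half-degraded cue retrieves nothing beyond itself
(accuracy ≈ 0, weight SNR = 1). After 30 presentations per pattern the
within-assembly weights stand 33× above the rest of the network
(≈ 41% of them saturated at w*max), and cueing half of each assembly
recruits the remainder: reconstruction accuracy ≈ 70%.

The same pipeline is scriptable from the shell:

```
ca3net train --config desk_scale --assembly-size 50 --presentations 30 \
             --seed 1 --out runs/demo
ca3net test  --train-dir runs/demo --checkpoint ckpt_30 --degradation 50 \
             --seed 0 --out runs/demo/metrics.tsv
```

(`ca3net analyze --metrics <table.tsv>` locates the most-effective-learning
point of any learning-curve table with `presentations` and
`accuracy_mean` columns, e.g. one assembled by testing each checkpoint.)

## Layout

- `ca3net.network_builder` — configurations, populations, Bernoulli
  wiring, assemblies, plasticity constants, scaling.
- `ca3net.dynamics_engine` — RK4 neuron integration, event-based
  Tsodyks–Markram synapses, the network simulator.
- `ca3net.plasticity` — symmetric STDP (kernel, traces, clipping) and
  divisive downscaling.
- `ca3net.protocols` — patterns, theta-gamma schedules, cue degradation,
  background sampling, training/testing phase runners, checkpoints.
- `ca3net.metrics` — activity vectors, reconstruction accuracy, SNR,
  saturation, firing rates, learning-curve inflection, capacity formulas.
- `ca3net.experiment`, `ca3net.cli` — orchestration and the `ca3net`
  command-line tool.
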