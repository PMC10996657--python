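"""Construction of CA3 network instances.

This module turns a declarative circuit configuration (neuron types with
Izhikevich parameters and lognormal background-current laws, directional
connection types with Tsodyks-Markram parameters and Bernoulli wiring
probabilities) into a concrete :class:`NetworkInstance`: a neuron table,
a sparse synapse table per connection type, cell-assembly assignments and
the long-term-plasticity constants tied to the chosen assembly size.

The maximum weight of a plastic pyramidal-to-pyramidal synapse scales
inversely with assembly size, ``w_max = 6000 / size`` (anchored so that an
assembly of 300 cells has ``w_max = 20``), and the potentiation amplitude
``A = (w_max - w_init) / 400`` lets a synapse climb from ``w_init = 0.625``
to ``w_max`` over 100 presentations of 4 coincident spikes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "IzhikevichParams",
    "BackgroundCurrentSpec",
    "NeuronTypeSpec",
    "TMSynapseParams",
    "ConnectionSpec",
    "PlasticityConstants",
    "AssemblySpec",
    "SynapsePopulation",
    "NetworkConfig",
    "NetworkInstance",
    "round_half_up",
    "load_config",
    "builtin_config_path",
    "build_populations",
    "wire_connections",
    "derive_plasticity_constants",
    "assign_assemblies",
    "scale_network",
    "build_network",
]

PC_TYPE = "Pyramidal"

#: default anchor of the inverse-proportional maximum-weight rule
WEIGHT_BUDGET = 6000.0
W_INIT = 0.625
TRAINING_SPIKES = 400.0


class ConfigurationError(ValueError):
    """Raised when a network configuration violates its contract."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1).

    Used everywhere a fractional cell count must become an integer, so that
    e.g. half of a 275-cell assembly is 138 cells.
    """
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IzhikevichParams:
    """Nine-parameter quadratic integrate-and-fire neuron constants.

    C is the membrane capacitance (pF); k scales the quadratic spike-
    generation term; vr and vt are the resting and instantaneous-threshold
    potentials (mV); a and b govern the recovery variable; d is the
    post-spike recovery increment; vpeak is the spike cutoff and vmin the
    post-spike reset potential (mV).
    """

    C: float
    k: float
    vr: float
    vt: float
    a: float
    b: float
    d: float
    vpeak: float
    vmin: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError(f"membrane capacitance must be positive, got {self.C}")
        if not (self.vr < self.vt < self.vpeak):
            raise ConfigurationError(
                f"require vr < vt < vpeak, got vr={self.vr}, vt={self.vt}, vpeak={self.vpeak}"
            )
        if not self.vmin < self.vpeak:
            raise ConfigurationError(f"require vmin < vpeak, got {self.vmin} >= {self.vpeak}")


@dataclass(frozen=True)
class BackgroundCurrentSpec:
    """Lognormal background-current law: ln(I) ~ Normal(mu, sigma2).

    ``mu_presentation``/``sigma2_presentation`` override the law for
    pyramidal cells while an input pattern is being presented.
    """

    mu: float
    sigma2: float
    mu_presentation: float | None = None
    sigma2_presentation: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ConfigurationError(f"sigma2 must be non-negative, got {self.sigma2}")
        if self.sigma2_presentation is not None and self.sigma2_presentation < 0:
            raise ConfigurationError("sigma2_presentation must be non-negative")

    @property
    def has_presentation_override(self) -> bool:
        return self.mu_presentation is not None or self.sigma2_presentation is not None


@dataclass(frozen=True)
class NeuronTypeSpec:
    name: str
    count: int
    izh: IzhikevichParams
    background: BackgroundCurrentSpec
    is_excitatory: bool = False

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigurationError(f"population count for {self.name!r} must be >= 1")


@dataclass(frozen=True)
class TMSynapseParams:
    """Five-parameter Tsodyks-Markram unitary synapse.

    g: unitary conductance (nS); tau_d: conductance decay (ms); tau_r:
    resource recovery (ms); tau_f: utilization decay (ms); U: baseline
    utilization fraction.
    """

    g: float
    tau_d: float
    tau_r: float
    tau_f: float
    U: float

    def __post_init__(self) -> None:
        if min(self.tau_d, self.tau_r, self.tau_f) <= 0:
            raise ConfigurationError("TM time constants must be positive")
        if not (0 < self.U < 1):
            raise ConfigurationError(f"U must lie in (0, 1), got {self.U}")
        if self.g <= 0:
            raise ConfigurationError(f"unitary conductance must be positive, got {self.g}")


@dataclass(frozen=True)
class ConnectionSpec:
    pre_type: str
    post_type: str
    probability: float
    tm: TMSynapseParams
    delay: float = 1.0
    plastic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ConfigurationError(
                f"connection probability for {self.pre_type}->{self.post_type} "
                f"must be in [0, 1], got {self.probability}"
            )
        if self.delay <= 0:
            raise ConfigurationError("synaptic delay must be positive")


@dataclass(frozen=True)
class PlasticityConstants:
    """Assembly-size-dependent long-term plasticity constants."""

    w_max: float
    A: float
    w_init: float
    g_max: float
    tau: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.w_init <= self.w_max):
            raise ConfigurationError(
                f"require 0 < w_init <= w_max, got w_init={self.w_init}, w_max={self.w_max}"
            )


@dataclass
class AssemblySpec:
    """Membership of one cell assembly, with pairwise-shared subsets."""

    assembly_id: int
    member_ids: np.ndarray
    shared_with: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(self.member_ids.size)

    @property
    def shared_ids(self) -> np.ndarray:
        if not self.shared_with:
            return np.empty(0, dtype=self.member_ids.dtype)
        return np.sort(np.concatenate(list(self.shared_with.values())))

    @property
    def unique_ids(self) -> np.ndarray:
        return np.setdiff1d(self.member_ids, self.shared_ids)


@dataclass
class SynapsePopulation:
    """All synapses of one directional connection type, CSR by presynaptic cell.

    ``indptr`` has length ``n_pre + 1`` (local presynaptic indices);
    ``targets`` holds global postsynaptic neuron indices.  ``weights`` is
    present only for the plastic population and is aligned with ``targets``.
    """

    spec: ConnectionSpec
    indptr: np.ndarray
    targets: np.ndarray
    weights: np.ndarray | None = None

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    def out_targets(self, local_pre: int) -> np.ndarray:
        return self.targets[self.indptr[local_pre]: self.indptr[local_pre + 1]]


@dataclass
class NetworkConfig:
    """Declarative description of the circuit, prior to instantiation."""

    neuron_types: dict[str, NeuronTypeSpec]
    connections: dict[tuple[str, str], ConnectionSpec]
    w_init: float = W_INIT
    weight_budget: float = WEIGHT_BUDGET
    training_spikes: float = TRAINING_SPIKES
    tau_ms: float = 20.0
    E_exc: float = 0.0
    E_inh: float = -70.0
    #: optional slow NMDA-type conductance component at recurrent PC->PC
    #: synapses: this fraction of each delivery decays with nmda_tau
    #: instead of the fast TM decay constant (0 = single receptor class)
    nmda_fraction: float = 0.0
    nmda_tau: float = 150.0
    scale_factor: float = 1.0
    scale_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.neuron_types) == 0:
            raise ConfigurationError("configuration lists no neuron types")
        for (pre, post), spec in self.connections.items():
            if (pre, post) != (spec.pre_type, spec.post_type):
                raise ConfigurationError(f"connection key {(pre, post)} does not match its spec")
            for name in (pre, post):
                if name not in self.neuron_types:
                    raise ConfigurationError(f"connection references unknown type {name!r}")

    @property
    def type_names(self) -> list[str]:
        return list(self.neuron_types)

    @property
    def total_neurons(self) -> int:
        return sum(t.count for t in self.neuron_types.values())

    def pc_pc_conductance(self) -> float:
        key = (PC_TYPE, PC_TYPE)
        if key not in self.connections:
            raise ConfigurationError("configuration has no Pyramidal->Pyramidal connection")
        return self.connections[key].tm.g

    def content_hash(self) -> str:
        """Stable hash of the configuration content (order-independent)."""
        blob = yaml.safe_dump(_config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class NetworkInstance:
    """A concrete network: neurons, synapses, assemblies, plasticity constants."""

    config: NetworkConfig
    neuron_type_ids: np.ndarray          # per-neuron type index into config.type_names
    type_offsets: dict[str, int]         # first global index of each type block
    synapses: dict[tuple[str, str], SynapsePopulation]
    assemblies: list[AssemblySpec]
    plasticity: PlasticityConstants
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.neuron_type_ids.size)

    @property
    def pc_slice(self) -> slice:
        start = self.type_offsets[PC_TYPE]
        return slice(start, start + self.config.neuron_types[PC_TYPE].count)

    @property
    def plastic_population(self) -> SynapsePopulation:
        return self.synapses[(PC_TYPE, PC_TYPE)]

    @property
    def plastic_weights(self) -> np.ndarray:
        w = self.plastic_population.weights
        assert w is not None
        return w

    def neuron_table(self) -> pd.DataFrame:
        names = self.config.type_names
        types = [names[i] for i in self.neuron_type_ids]
        df = pd.DataFrame({"neuron_id": np.arange(self.n_neurons), "type": types})
        param_rows = {
            name: self.config.neuron_types[name].izh for name in names
        }
        for f in ("C", "k", "vr", "vt", "a", "b", "d", "vpeak", "vmin"):
            df[f] = [getattr(param_rows[t], f) for t in types]
        return df

    def synapse_table(self) -> pd.DataFrame:
        """Flat (pre, post, weight, delay, plastic) view of every synapse."""
        frames = []
        for (pre, post), pop in self.synapses.items():
            n_pre = len(pop.indptr) - 1
            pre_local = np.repeat(np.arange(n_pre), np.diff(pop.indptr))
            pre_global = pre_local + self.type_offsets[pre]
            w = pop.weights if pop.weights is not None else np.ones(pop.n_synapses)
            frames.append(pd.DataFrame({
                "pre": pre_global, "post": pop.targets, "weight": w,
                "delay": pop.spec.delay, "plastic": pop.spec.plastic,
                "pre_type": pre, "post_type": post,
            }))
        if not frames:
            return pd.DataFrame(columns=["pre", "post", "weight", "delay", "plastic",
                                         "pre_type", "post_type"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

def builtin_config_path(name: str):
    """Path to a configuration shipped with the package (e.g. 'desk_scale')."""
    return resources.files("ca3net.configs").joinpath(f"{name}.yaml")


def load_config(source, apply_scale: bool = True) -> NetworkConfig:
    """Load a network configuration from a YAML file, path, or mapping.

    If the configuration carries a ``scale`` section with factor < 1 and
    ``apply_scale`` is true, :func:`scale_network` is applied so that the
    returned configuration is ready to instantiate.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        text = source.read_text() if hasattr(source, "read_text") else open(source).read()
        raw = yaml.safe_load(text)
    try:
        types: dict[str, NeuronTypeSpec] = {}
        for name, t in raw["neuron_types"].items():
            types[name] = NeuronTypeSpec(
                name=name,
                count=int(t["count"]),
                izh=IzhikevichParams(**t["izhikevich"]),
                background=BackgroundCurrentSpec(**t["background"]),
                is_excitatory=bool(t.get("excitatory", False)),
            )
        conns: dict[tuple[str, str], ConnectionSpec] = {}
        for c in raw["connections"]:
            key = (c["pre"], c["post"])
            if key in conns:
                raise ConfigurationError(f"duplicate connection spec for {key}")
            conns[key] = ConnectionSpec(
                pre_type=c["pre"], post_type=c["post"],
                probability=float(c["probability"]),
                delay=float(c.get("delay", 1.0)),
                plastic=bool(c.get("plastic", False)),
                tm=TMSynapseParams(**c["tm"]),
            )
    except KeyError as exc:
        raise ConfigurationError(f"configuration is missing required field {exc}") from exc
    plast = raw.get("plasticity", {})
    rev = raw.get("reversal_potentials", {})
    cfg = NetworkConfig(
        neuron_types=types,
        connections=conns,
        w_init=float(plast.get("w_init", W_INIT)),
        weight_budget=float(plast.get("weight_budget", WEIGHT_BUDGET)),
        training_spikes=float(plast.get("training_spikes", TRAINING_SPIKES)),
        tau_ms=float(plast.get("tau_ms", 20.0)),
        E_exc=float(rev.get("E_exc", 0.0)),
        E_inh=float(rev.get("E_inh", -70.0)),
        nmda_fraction=float(raw.get("synapses", {}).get("nmda_fraction", 0.0)),
        nmda_tau=float(raw.get("synapses", {}).get("nmda_tau", 150.0)),
        scale_factor=float(raw.get("scale", {}).get("factor", 1.0)),
    )
    if apply_scale and cfg.scale_factor != 1.0:
        cfg = scale_network(cfg, cfg.scale_factor, _already_declared=True)
    return cfg


def _config_to_dict(cfg: NetworkConfig) -> dict:
    return {
        "neuron_types": {
            name: {
                "count": t.count,
                "excitatory": t.is_excitatory,
                "izhikevich": vars(t.izh).copy(),
                "background": {k: v for k, v in vars(t.background).items() if v is not None},
            }
            for name, t in cfg.neuron_types.items()
        },
        "connections": [
            {
                "pre": s.pre_type, "post": s.post_type,
                "probability": s.probability, "delay": s.delay,
                "plastic": s.plastic, "tm": vars(s.tm).copy(),
            }
            for s in cfg.connections.values()
        ],
        "plasticity": {
            "w_init": cfg.w_init, "weight_budget": cfg.weight_budget,
            "training_spikes": cfg.training_spikes, "tau_ms": cfg.tau_ms,
        },
        "reversal_potentials": {"E_exc": cfg.E_exc, "E_inh": cfg.E_inh},
        "synapses": {"nmda_fraction": cfg.nmda_fraction, "nmda_tau": cfg.nmda_tau},
        "scale": {"factor": cfg.scale_factor},
    }


def save_config(cfg: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Build operations
# ---------------------------------------------------------------------------

def build_populations(config: NetworkConfig) -> pd.DataFrame:
    """Instantiate the neuron table: contiguous global indices grouped by type."""
    rows = []
    offset = 0
    for name, t in config.neuron_types.items():
        rows.append(pd.DataFrame({
            "neuron_id": np.arange(offset, offset + t.count),
            "type": name,
        }))
        offset += t.count
    df = pd.concat(rows, ignore_index=True)
    for f in ("C", "k", "vr", "vt", "a", "b", "d", "vpeak", "vmin"):
        df[f] = df["type"].map({n: getattr(t.izh, f) for n, t in config.neuron_types.items()})
    return df


def _type_offsets(config: NetworkConfig) -> dict[str, int]:
    offsets, acc = {}, 0
    for name, t in config.neuron_types.items():
        offsets[name] = acc
        acc += t.count
    return offsets


def wire_connections(
    config: NetworkConfig,
    rng: np.random.Generator | int | None,
    w_init: float | None = None,
) -> dict[tuple[str, str], SynapsePopulation]:
    """Realize Bernoulli wiring for every connection spec.

    Each ordered (pre, post) neuron pair of a wired type pair is connected
    independently with the spec's probability; autapses are excluded; at
    most one synapse exists per ordered pair.  Plastic synapses start at
    ``w_init``; non-plastic synapse weights are implicitly 1.
    """
    rng = np.random.default_rng(rng)
    if w_init is None:
        w_init = config.w_init
    offsets = _type_offsets(config)
    out: dict[tuple[str, str], SynapsePopulation] = {}
    for key in sorted(config.connections):  # deterministic draw order
        spec = config.connections[key]
        n_pre = config.neuron_types[spec.pre_type].count
        n_post = config.neuron_types[spec.post_type].count
        post0 = offsets[spec.post_type]
        autapse = spec.pre_type == spec.post_type
        counts = np.zeros(n_pre, dtype=np.int64)
        target_chunks = []
        if spec.probability > 0:
            # chunk over presynaptic cells to bound the Bernoulli matrix size
            chunk = max(1, int(4e6 // max(n_post, 1)))
            for lo in range(0, n_pre, chunk):
                hi = min(lo + chunk, n_pre)
                mask = rng.random((hi - lo, n_post)) < spec.probability
                if autapse:
                    rows = np.arange(lo, hi)
                    mask[np.arange(hi - lo), rows] = False
                pre_rel, post_rel = np.nonzero(mask)
                counts[lo:hi] = np.bincount(pre_rel, minlength=hi - lo)
                target_chunks.append((post_rel + post0).astype(np.int32))
        targets = (np.concatenate(target_chunks) if target_chunks
                   else np.empty(0, dtype=np.int32))
        indptr = np.concatenate(([0], np.cumsum(counts)))
        weights = None
        if spec.plastic:
            weights = np.full(targets.size, w_init, dtype=np.float64)
        out[key] = SynapsePopulation(spec=spec, indptr=indptr, targets=targets,
                                     weights=weights)
    return out


def derive_plasticity_constants(
    assembly_size: int,
    g_pc_pc: float = 0.55,
    w_init: float = W_INIT,
    weight_budget: float = WEIGHT_BUDGET,
    training_spikes: float = TRAINING_SPIKES,
    tau: float = 20.0,
) -> PlasticityConstants:
    """Plasticity constants for a given assembly size.

    ``w_max = weight_budget / size`` (inverse proportionality: the larger
    the assembly, the more convergent presynaptic members, the smaller each
    unitary maximum must be) and ``A = (w_max - w_init) / training_spikes``
    (a synapse reaches ``w_max`` from ``w_init`` if all of the 100 x 4
    training spikes coincide exactly).  Values are returned unrounded.
    """
    if assembly_size <= 0:
        raise ValueError(f"assembly size must be positive, got {assembly_size}")
    w_max = weight_budget / assembly_size
    if w_max < w_init:
        raise ConfigurationError(
            f"assembly size {assembly_size} yields w_max={w_max} below w_init={w_init}"
        )
    A = (w_max - w_init) / training_spikes
    return PlasticityConstants(w_max=w_max, A=A, w_init=w_init,
                               g_max=w_max * g_pc_pc, tau=tau)


def assign_assemblies(
    pc_indices: np.ndarray,
    n_assemblies: int,
    size: int,
    overlap_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[AssemblySpec]:
    """Randomly select assembly memberships with exact pairwise overlap.

    With overlap fraction ``f`` every unordered pair of assemblies shares
    exactly ``round_half_up(f * size)`` cells; the pairwise shared sets are
    mutually disjoint (no cell belongs to three assemblies) and all other
    members are unique to one assembly.
    """
    pc_indices = np.asarray(pc_indices)
    rng = np.random.default_rng(rng)
    if not (0 <= overlap_fraction < 1):
        raise ConfigurationError(f"overlap fraction must be in [0, 1), got {overlap_fraction}")
    n_shared = round_half_up(overlap_fraction * size) if n_assemblies > 1 else 0
    n_unique = size - (n_assemblies - 1) * n_shared
    if n_unique < 0:
        raise ConfigurationError(
            f"assembly size {size} cannot host {n_assemblies - 1} shared subsets of {n_shared}"
        )
    pairs = [(i, j) for i in range(n_assemblies) for j in range(i + 1, n_assemblies)]
    n_needed = n_assemblies * n_unique + len(pairs) * n_shared
    if n_needed > pc_indices.size:
        raise ConfigurationError(
            f"need {n_needed} distinct PCs for {n_assemblies} assemblies of {size} "
            f"with overlap {overlap_fraction}, only {pc_indices.size} available"
        )
    pool = rng.permutation(pc_indices)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        sel = pool[cursor:cursor + n]
        cursor += n
        return np.sort(sel)

    shared: dict[tuple[int, int], np.ndarray] = {p: take(n_shared) for p in pairs}
    assemblies = []
    for a in range(n_assemblies):
        own_shared = {other: s for (i, j), s in shared.items()
                      for other in ((j,) if i == a else (i,) if j == a else ())}
        members = np.sort(np.concatenate(
            [take(n_unique)] + [s for s in own_shared.values()]
        ))
        assemblies.append(AssemblySpec(assembly_id=a, member_ids=members,
                                       shared_with=own_shared))
    return assemblies


def scale_network(config: NetworkConfig, factor: float,
                  _already_declared: bool = False) -> NetworkConfig:
    """Shrink a configuration while preserving expected in-degrees.

    Population counts are multiplied by ``factor`` (rounded half-up, minimum
    1) and connection probabilities by ``1/factor`` capped at 1, so the
    expected number of inputs per postsynaptic cell from each presynaptic
    type is unchanged.  A warning string is attached to the returned config
    for every probability that hits the cap.

    The plastic weight budget is multiplied by ``sqrt(factor)``.  Two
    invariants compete when probabilities are inflated by ``1/factor`` at
    unchanged absolute assembly size: keeping the mean saturated convergent
    drive ``(c * size) * w_max`` at its full-scale value requires
    ``budget * factor`` (an unscaled budget makes reduced-scale training
    epileptic), while keeping the unitary synaptic efficacy ``w_max * g``
    that drives sparse-connectivity pattern completion requires an
    unscaled budget (a fully scaled one leaves recruitment currents too
    weak to complete patterns).  The geometric mean preserves both
    behaviours at reduced scale.
    """
    if not (0 < factor <= 1):
        raise ConfigurationError(f"scale factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return config
    warnings: list[str] = []
    new_types = {
        name: replace(t, count=max(1, round_half_up(t.count * factor)))
        for name, t in config.neuron_types.items()
    }
    new_conns = {}
    for key, spec in config.connections.items():
        p = spec.probability / factor
        if p > 1.0:
            warnings.append(
                f"{spec.pre_type}->{spec.post_type}: scaled probability "
                f"{p:.3g} capped at 1; expected in-degree no longer preserved"
            )
            p = 1.0
        new_conns[key] = replace(spec, probability=p)
    return replace(
        config,
        neuron_types=new_types,
        connections=new_conns,
        weight_budget=config.weight_budget * math.sqrt(factor),
        scale_factor=factor if _already_declared else config.scale_factor * factor,
        scale_warnings=config.scale_warnings + warnings,
    )


def build_network(
    config: NetworkConfig,
    assembly_size: int,
    n_assemblies: int = 3,
    overlap_fraction: float = 0.0,
    seed: int | None = None,
) -> NetworkInstance:
    """Wire a full :class:`NetworkInstance` from a configuration."""
    ss = np.random.SeedSequence(seed)
    rng_wiring, rng_assembly = (np.random.default_rng(s) for s in ss.spawn(2))
    plasticity = derive_plasticity_constants(
        assembly_size,
        g_pc_pc=config.pc_pc_conductance(),
        w_init=config.w_init,
        weight_budget=config.weight_budget,
        training_spikes=config.training_spikes,
        tau=config.tau_ms,
    )
    offsets = _type_offsets(config)
    type_ids = np.repeat(
        np.arange(len(config.neuron_types)),
        [t.count for t in config.neuron_types.values()],
    )
    synapses = wire_connections(config, rng_wiring, w_init=config.w_init)
    pc0 = offsets[PC_TYPE]
    pc_ids = np.arange(pc0, pc0 + config.neuron_types[PC_TYPE].count)
    assemblies = assign_assemblies(pc_ids, n_assemblies, assembly_size,
                                   overlap_fraction, rng_assembly)
    return NetworkInstance(
        config=config,
        neuron_type_ids=type_ids,
        type_offsets=offsets,
        synapses=synapses,
        assemblies=assemblies,
        plasticity=plasticity,
        seed=seed,
    )
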