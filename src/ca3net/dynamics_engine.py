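"""Clock-driven integration of the CA3 network.

Neurons follow the 9-parameter Izhikevich quadratic model,

    C dv/dt = k (v - vr)(v - vt) - u + I
      du/dt = a (b (v - vr) - u)

integrated with classical fixed-step 4th-order Runge-Kutta (default
dt = 0.2 ms) with currents held constant across each step.  When v reaches
vpeak a spike is recorded, v resets to vmin and u increments by d.

Synapses follow the event-based 5-parameter Tsodyks-Markram model.  On
arrival of a presynaptic spike (emission + 1 ms):

    u+ = u + U (1 - u)
    g_syn += w * g * u+ * x
    x <- x (1 - u+)
    u <- u+

with exact exponential relaxation between events (g_syn decays with tau_d,
x recovers to 1 with tau_r, u decays to 0 with tau_f).  Because u and x
depend only on the presynaptic spike history, they are stored once per
presynaptic cell and connection type rather than per synapse.  Synaptic
conductances are conductance-based: I_syn = sum_class g_class (E_class - v)
with E_exc = 0 mV and E_inh = -70 mV by default.

Plasticity (when enabled) applies the symmetric STDP rule online at spike
emission times using per-neuron traces; see :mod:`ca3net.plasticity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_builder import (
    PC_TYPE,
    IzhikevichParams,
    NetworkInstance,
    TMSynapseParams,
)
from .plasticity import STDPRule

__all__ = [
    "NeuronState",
    "TMSynapseState",
    "SpikeRecord",
    "Drive",
    "IntegrationError",
    "izhikevich_derivatives",
    "step_rk4",
    "detect_spike_and_reset",
    "deliver_spike_tm",
    "relax_tm_between_events",
    "total_synaptic_current",
    "Simulator",
    "run_simulation",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class NeuronState:
    """Membrane potential v (mV) and recovery variable u; scalar or array."""

    v: np.ndarray | float
    u: np.ndarray | float


@dataclass
class TMSynapseState:
    u_stp: float = 0.0
    x_stp: float = 1.0
    g_syn: float = 0.0


@dataclass
class SpikeRecord:
    """Ordered spike events plus simulation metadata."""

    neuron_ids: np.ndarray
    times: np.ndarray
    dt: float
    duration: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def counts(self, n_neurons: int, t0: float = -np.inf, t1: float = np.inf) -> np.ndarray:
        """Per-neuron spike counts within [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1)
        return np.bincount(self.neuron_ids[m], minlength=n_neurons)

    def to_dataframe(self, type_names=None):
        import pandas as pd

        df = pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times})
        if type_names is not None:
            df.insert(1, "type", np.asarray(type_names)[self.neuron_ids])
        return df

    def write_tsv(self, path, type_names=None) -> None:
        self.to_dataframe(type_names).to_csv(path, sep="\t", index=False)


@dataclass
class Drive:
    """Compiled external input for one simulation run.

    ``pulse_steps``/``pulse_neurons`` list the starts of stimulation pulses
    (sorted by step).  In ``forced`` mode the scheduled neurons spike
    exactly at the scheduled step instead of receiving current.
    ``presentation_windows`` are (start_step, end_step) half-open intervals
    during which pyramidal cells draw their presentation background
    current.
    """

    pulse_steps: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pulse_neurons: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pulse_amplitude: float = 4000.0
    pulse_duration_ms: float = 2.0
    forced: bool = False
    presentation_windows: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), np.int64))


# ---------------------------------------------------------------------------
# Elementary operations (scalar/array)
# ---------------------------------------------------------------------------

def izhikevich_derivatives(state: NeuronState, params: IzhikevichParams, I_total):
    """(dv/dt, du/dt) of the quadratic two-variable neuron model."""
    v, u = state.v, state.u
    dv = (params.k * (v - params.vr) * (v - params.vt) - u + I_total) / params.C
    du = params.a * (params.b * (v - params.vr) - u)
    return dv, du


def step_rk4(state: NeuronState, params: IzhikevichParams, I_total, dt: float) -> NeuronState:
    """One classical RK4 step of the coupled (v, u) system, current held fixed."""
    if dt <= 0:
        raise ValueError("dt must be positive")

    def f(v, u):
        return izhikevich_derivatives(NeuronState(v, u), params, I_total)

    v, u = state.v, state.u
    k1v, k1u = f(v, u)
    k2v, k2u = f(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u)
    k3v, k3u = f(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u)
    k4v, k4u = f(v + dt * k3v, u + dt * k3u)
    v1 = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    u1 = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
    bad = ~np.isfinite(np.atleast_1d(v1))
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise IntegrationError(f"non-finite membrane potential at neuron index {idx}")
    return NeuronState(v1, u1)


def detect_spike_and_reset(state: NeuronState, params: IzhikevichParams):
    """Threshold crossing: v >= vpeak -> reset v to vmin, u += d."""
    v = np.atleast_1d(np.asarray(state.v, dtype=float)).copy()
    u = np.atleast_1d(np.asarray(state.u, dtype=float)).copy()
    spiked = v >= params.vpeak
    v[spiked] = params.vmin
    u[spiked] += params.d
    if np.isscalar(state.v) or np.ndim(state.v) == 0:
        return NeuronState(float(v[0]), float(u[0])), bool(spiked[0])
    return NeuronState(v, u), spiked


def deliver_spike_tm(syn: TMSynapseState, tm: TMSynapseParams, w: float) -> TMSynapseState:
    """Apply one presynaptic spike arrival to a TM synapse state."""
    u_plus = syn.u_stp + tm.U * (1.0 - syn.u_stp)
    g_new = syn.g_syn + w * tm.g * u_plus * syn.x_stp
    x_new = syn.x_stp * (1.0 - u_plus)
    return TMSynapseState(u_stp=u_plus, x_stp=x_new, g_syn=g_new)


def relax_tm_between_events(syn: TMSynapseState, tm: TMSynapseParams,
                            elapsed: float) -> TMSynapseState:
    """Exact exponential relaxation of (u, x, g) over ``elapsed`` ms.

    Accepts scalar or per-synapse array state/elapsed values.
    """
    if np.any(np.asarray(elapsed) < 0):
        raise ValueError("elapsed time must be non-negative")
    return TMSynapseState(
        u_stp=syn.u_stp * np.exp(-elapsed / tm.tau_f),
        x_stp=1.0 - (1.0 - syn.x_stp) * np.exp(-elapsed / tm.tau_r),
        g_syn=syn.g_syn * np.exp(-elapsed / tm.tau_d),
    )


def total_synaptic_current(v_post, g_exc, g_inh, E_exc: float = 0.0, E_inh: float = -70.0):
    """Conductance-based closure: I = g_exc (E_exc - v) + g_inh (E_inh - v), pA."""
    return g_exc * (E_exc - v_post) + g_inh * (E_inh - v_post)


# ---------------------------------------------------------------------------
# Network simulator
# ---------------------------------------------------------------------------

class _PairState:
    """Per-connection-type runtime state (TM variables per presynaptic cell)."""

    __slots__ = ("key", "tm", "plastic", "indptr", "targets", "slots",
                 "slots_slow", "u", "x", "last_step", "exc")

    def __init__(self, key, tm, plastic, indptr, targets, slots, exc):
        self.key = key
        self.tm = tm
        self.plastic = plastic
        self.indptr = indptr
        self.targets = targets      # global post ids
        self.slots = slots          # indices into the exc or inh conductance buffer
        self.slots_slow = None      # NMDA-component slots (plastic pair only)
        self.exc = exc
        n_pre = len(indptr) - 1
        self.u = np.zeros(n_pre)
        self.x = np.ones(n_pre)
        self.last_step = np.zeros(n_pre, dtype=np.int64)


class Simulator:
    """Stateful clock-driven simulator over a :class:`NetworkInstance`.

    The simulator references (and, with plasticity enabled, mutates) the
    network's plastic weight vector.  All randomness is injected through
    the background-current vectors; stepping is fully deterministic.
    """

    def __init__(
        self,
        network: NetworkInstance,
        dt: float = 0.2,
        plasticity_on: bool = False,
        background: np.ndarray | None = None,
        background_presentation: np.ndarray | None = None,
        background_starts: np.ndarray | None = None,
        drive: Drive | None = None,
        stdp_rule: STDPRule | None = None,
        stdp_windows_only: bool = False,
    ):
        cfg = network.config
        self.network = network
        self.dt = float(dt)
        self.plasticity_on = bool(plasticity_on)
        #: restrict STDP to spikes emitted inside presentation windows
        #: (encoding-phase gating); spikes outside the windows neither
        #: update weights nor enter the pairing traces
        self.stdp_windows_only = bool(stdp_windows_only)
        self.drive = drive if drive is not None else Drive()
        n = network.n_neurons
        self.n_neurons = n

        names = cfg.type_names
        type_ids = network.neuron_type_ids
        self._params = {}
        for f in ("C", "k", "vr", "vt", "a", "b", "d", "vpeak", "vmin"):
            vals = np.array([getattr(cfg.neuron_types[t].izh, f) for t in names])
            self._params[f] = vals[type_ids]
        self.v = self._params["vr"].copy()
        self.u = np.zeros(n)

        delays = {spec.spec.delay for spec in network.synapses.values()}
        if len(delays) > 1:
            raise NotImplementedError("simulator assumes one uniform synaptic delay")
        delay_ms = delays.pop() if delays else 1.0
        self.delay_steps = max(1, int(round(delay_ms / self.dt)))

        # flat conductance buffers: one slot per (connection type, post cell)
        exc_decay, inh_decay = [], []
        exc_post, inh_post = [], []
        self.pairs: list[_PairState] = []
        self.pairs_by_pre_type: dict[int, list[_PairState]] = {
            i: [] for i in range(len(names))}
        for key in sorted(network.synapses):
            pop = network.synapses[key]
            if pop.n_synapses == 0:
                continue
            pre_name, post_name = key
            exc = cfg.neuron_types[pre_name].is_excitatory
            n_post = cfg.neuron_types[post_name].count
            post0 = network.type_offsets[post_name]
            decay_list, post_list = (exc_decay, exc_post) if exc else (inh_decay, inh_post)
            offset = sum(len(a) for a in post_list)
            slots = offset + (pop.targets - post0)
            decay_list.append(np.full(n_post, np.exp(-self.dt / pop.spec.tm.tau_d)))
            post_list.append(np.arange(post0, post0 + n_post))
            ps = _PairState(key, pop.spec.tm, pop.spec.plastic,
                            pop.indptr, pop.targets, slots, exc)
            if pop.spec.plastic and cfg.nmda_fraction > 0:
                # slow NMDA-type component at recurrent synapses: a second
                # slot block in the excitatory buffer with its own decay
                offset2 = sum(len(a) for a in post_list)
                ps.slots_slow = offset2 + (pop.targets - post0)
                decay_list.append(np.full(n_post, np.exp(-self.dt / cfg.nmda_tau)))
                post_list.append(np.arange(post0, post0 + n_post))
            self.pairs.append(ps)
            self.pairs_by_pre_type[names.index(pre_name)].append(ps)
        self._g_exc_buf = np.zeros(sum(len(a) for a in exc_post))
        self._g_inh_buf = np.zeros(sum(len(a) for a in inh_post))
        self._exc_decay = (np.concatenate(exc_decay) if exc_decay else np.empty(0))
        self._inh_decay = (np.concatenate(inh_decay) if inh_decay else np.empty(0))
        self._exc_post = (np.concatenate(exc_post) if exc_post else np.empty(0, np.int64))
        self._inh_post = (np.concatenate(inh_post) if inh_post else np.empty(0, np.int64))
        self.E_exc, self.E_inh = cfg.E_exc, cfg.E_inh
        self._nmda_frac = cfg.nmda_fraction

        # plastic pair bookkeeping (incoming CSC view for STDP)
        self._plastic = None
        for ps in self.pairs:
            if ps.plastic:
                self._plastic = ps
        self.w = network.plastic_weights if self._plastic is not None else None
        if self._plastic is not None:
            self._build_csc()
        pc0 = network.type_offsets[PC_TYPE]
        self._pc0 = pc0
        self._n_pc = cfg.neuron_types[PC_TYPE].count
        if stdp_rule is None:
            pl = network.plasticity
            stdp_rule = STDPRule(A=pl.A, tau=pl.tau, w_min=0.0, w_max=pl.w_max)
        self.stdp_rule = stdp_rule
        self._trace_val = np.zeros(self._n_pc)
        self._trace_t = np.full(self._n_pc, -np.inf)

        # backgrounds: (n,) static vectors, or (k, n) stacks redrawn at the
        # step indices in background_starts (sorted; first entry covers the
        # beginning of the run)
        if background is None:
            background = np.zeros(n)
        self.background = np.atleast_2d(background)
        self.background_presentation = (
            None if background_presentation is None
            else np.atleast_2d(background_presentation))
        if background_starts is None:
            background_starts = np.zeros(self.background.shape[0], dtype=np.int64)
        self._bg_starts = np.asarray(background_starts, dtype=np.int64)
        if self._bg_starts.size != self.background.shape[0]:
            raise ValueError("background_starts does not match background draws")
        self._bg_ptr = 0

        # ring slot i % (delay+1) is written at the end of step i (emission
        # time (i+1) dt) and read at the start of step i + delay + 1, i.e.
        # arrival exactly delay ms after emission
        self._ring: list[np.ndarray] = [np.empty(0, np.int64)
                                        for _ in range(self.delay_steps + 1)]
        self._pulse_until = np.full(n, -1, dtype=np.int64)
        self._drive_ptr = 0
        self._window_ptr = 0
        self.step_index = 0
        self._spike_ids: list[np.ndarray] = []
        self._spike_times: list[np.ndarray] = []

    # -- construction helpers ------------------------------------------------

    def _build_csc(self) -> None:
        ps = self._plastic
        n_pre = len(ps.indptr) - 1
        pre_local = np.repeat(np.arange(n_pre), np.diff(ps.indptr))
        post_local = ps.targets - self._post0_of(ps)
        order = np.argsort(post_local, kind="stable")
        self._csc_syn = order.astype(np.int64)          # synapse index by post
        self._csc_pre = pre_local[order].astype(np.int64)
        counts = np.bincount(post_local, minlength=self._plastic_n_post(ps))
        self._csc_indptr = np.concatenate(([0], np.cumsum(counts)))

    def _post0_of(self, ps: _PairState) -> int:
        return self.network.type_offsets[ps.key[1]]

    def _plastic_n_post(self, ps: _PairState) -> int:
        return self.network.config.neuron_types[ps.key[1]].count

    # -- state snapshot (for exact checkpoint/resume) ------------------------

    def get_state(self) -> dict:
        state = {
            "step": self.step_index,
            "v": self.v.copy(), "u": self.u.copy(),
            "g_exc": self._g_exc_buf.copy(), "g_inh": self._g_inh_buf.copy(),
            "trace_val": self._trace_val.copy(), "trace_t": self._trace_t.copy(),
            "ring": [r.copy() for r in self._ring],
            "pulse_until": self._pulse_until.copy(),
            "drive_ptr": self._drive_ptr, "window_ptr": self._window_ptr,
            "bg_ptr": self._bg_ptr,
            "pairs": [(p.u.copy(), p.x.copy(), p.last_step.copy()) for p in self.pairs],
        }
        if self.w is not None:
            state["w"] = self.w.copy()
        return state

    def set_state(self, state: dict) -> None:
        self.step_index = state["step"]
        self.v[:] = state["v"]
        self.u[:] = state["u"]
        self._g_exc_buf[:] = state["g_exc"]
        self._g_inh_buf[:] = state["g_inh"]
        self._trace_val[:] = state["trace_val"]
        self._trace_t[:] = state["trace_t"]
        self._ring = [r.copy() for r in state["ring"]]
        self._pulse_until[:] = state["pulse_until"]
        self._drive_ptr = state["drive_ptr"]
        self._window_ptr = state["window_ptr"]
        self._bg_ptr = state.get("bg_ptr", 0)
        for p, (pu, px, pl) in zip(self.pairs, state["pairs"]):
            p.u[:] = pu
            p.x[:] = px
            p.last_step[:] = pl
        if self.w is not None and "w" in state:
            self.w[:] = state["w"]

    # -- core loop -----------------------------------------------------------

    def _deliver(self, neuron_ids: np.ndarray) -> None:
        step = self.step_index
        offsets = self.network.type_offsets
        tids = self.network.neuron_type_ids
        for n in neuron_ids:
            for ps in self.pairs_by_pre_type[tids[n]]:
                lo = n - offsets[ps.key[0]]
                s, e = ps.indptr[lo], ps.indptr[lo + 1]
                if s == e:
                    continue
                elapsed = (step - ps.last_step[lo]) * self.dt
                tm = ps.tm
                if elapsed > 0:
                    ps.u[lo] *= np.exp(-elapsed / tm.tau_f)
                    ps.x[lo] = 1.0 - (1.0 - ps.x[lo]) * np.exp(-elapsed / tm.tau_r)
                ps.last_step[lo] = step
                u_plus = ps.u[lo] + tm.U * (1.0 - ps.u[lo])
                factor = tm.g * u_plus * ps.x[lo]
                ps.x[lo] *= (1.0 - u_plus)
                ps.u[lo] = u_plus
                buf = self._g_exc_buf if ps.exc else self._g_inh_buf
                if ps.plastic:
                    vals = factor * self.w[s:e]
                    if ps.slots_slow is not None:
                        rho = self._nmda_frac
                        buf[ps.slots[s:e]] += (1.0 - rho) * vals
                        buf[ps.slots_slow[s:e]] += rho * vals
                    else:
                        buf[ps.slots[s:e]] += vals
                else:
                    buf[ps.slots[s:e]] += factor

    def _apply_stdp(self, spiking: np.ndarray, t: float) -> None:
        """Online symmetric STDP at spike emission time t (all-pairs)."""
        pc = spiking[(spiking >= self._pc0) & (spiking < self._pc0 + self._n_pc)]
        if pc.size == 0:
            return
        pc_local = pc - self._pc0
        ps = self._plastic
        if ps is None:
            return
        A, tau = self.stdp_rule.A, self.stdp_rule.tau
        w_max = self.stdp_rule.w_max
        in_set = np.zeros(self._n_pc, dtype=bool)
        in_set[pc_local] = True

        def trace_at(ids):
            val = self._trace_val[ids]
            out = np.zeros(ids.size)
            nz = val > 0
            if nz.any():
                out[nz] = val[nz] * np.exp(-(t - self._trace_t[ids][nz]) / tau)
            return out

        for j in pc_local:
            # incoming synapses: pairs with earlier (or coincident) pre spikes
            s, e = self._csc_indptr[j], self._csc_indptr[j + 1]
            if e > s:
                pres = self._csc_pre[s:e]
                syn = self._csc_syn[s:e]
                dw = A * trace_at(pres) + A * in_set[pres]
                self.w[syn] = np.minimum(self.w[syn] + dw, w_max)
            # outgoing synapses: pairs with earlier post spikes only
            s, e = ps.indptr[j], ps.indptr[j + 1]
            if e > s:
                posts = ps.targets[s:e] - self._pc0
                self.w[s:e] = np.minimum(self.w[s:e] + A * trace_at(posts), w_max)
        # bump traces after all updates for this grid point
        decay = np.exp(-(t - self._trace_t[pc_local]) / self.stdp_rule.tau)
        old = np.where(self._trace_val[pc_local] > 0,
                       self._trace_val[pc_local] * decay, 0.0)
        self._trace_val[pc_local] = old + 1.0
        self._trace_t[pc_local] = t

    def run(self, n_steps: int) -> None:
        dt = self.dt
        drive = self.drive
        params = self._params
        C, k = params["C"], params["k"]
        vr, vt = params["vr"], params["vt"]
        a, b = params["a"], params["b"]
        d, vpeak, vmin = params["d"], params["vpeak"], params["vmin"]
        n = self.n_neurons
        pres_windows = drive.presentation_windows
        pulse_steps_len = int(round(drive.pulse_duration_ms / dt))

        for _ in range(n_steps):
            i = self.step_index
            # 1. conductance decay + queued deliveries (arriving this step)
            if self._g_exc_buf.size:
                self._g_exc_buf *= self._exc_decay
            if self._g_inh_buf.size:
                self._g_inh_buf *= self._inh_decay
            arriving = self._ring[i % (self.delay_steps + 1)]
            if arriving.size:
                self._deliver(arriving)

            # 2. external drive bookkeeping
            forced_now = np.empty(0, np.int64)
            while (self._drive_ptr < drive.pulse_steps.size
                   and drive.pulse_steps[self._drive_ptr] == i):
                pass_start = self._drive_ptr
                while (self._drive_ptr < drive.pulse_steps.size
                       and drive.pulse_steps[self._drive_ptr] == i):
                    self._drive_ptr += 1
                starters = drive.pulse_neurons[pass_start:self._drive_ptr]
                if drive.forced:
                    forced_now = starters
                else:
                    self._pulse_until[starters] = i + pulse_steps_len

            in_presentation = False
            while (self._window_ptr < len(pres_windows)
                   and pres_windows[self._window_ptr, 1] <= i):
                self._window_ptr += 1
            if (self._window_ptr < len(pres_windows)
                    and pres_windows[self._window_ptr, 0] <= i):
                in_presentation = True

            # 3. total current, held constant across the RK4 step
            if self._g_exc_buf.size:
                g_exc = np.bincount(self._exc_post, weights=self._g_exc_buf,
                                    minlength=n)
            else:
                g_exc = 0.0
            if self._g_inh_buf.size:
                g_inh = np.bincount(self._inh_post, weights=self._g_inh_buf,
                                    minlength=n)
            else:
                g_inh = 0.0
            I = total_synaptic_current(self.v, g_exc, g_inh, self.E_exc, self.E_inh)
            while (self._bg_ptr + 1 < self._bg_starts.size
                   and self._bg_starts[self._bg_ptr + 1] <= i):
                self._bg_ptr += 1
            if in_presentation and self.background_presentation is not None:
                I = I + self.background_presentation[self._bg_ptr]
            else:
                I = I + self.background[self._bg_ptr]
            active = self._pulse_until > i
            if active.any():
                I = I + np.where(active, drive.pulse_amplitude, 0.0)

            # 4. RK4 integration of all neurons
            v, u = self.v, self.u
            k1v = (k * (v - vr) * (v - vt) - u + I) / C
            k1u = a * (b * (v - vr) - u)
            v2 = v + 0.5 * dt * k1v
            u2 = u + 0.5 * dt * k1u
            k2v = (k * (v2 - vr) * (v2 - vt) - u2 + I) / C
            k2u = a * (b * (v2 - vr) - u2)
            v3 = v + 0.5 * dt * k2v
            u3 = u + 0.5 * dt * k2u
            k3v = (k * (v3 - vr) * (v3 - vt) - u3 + I) / C
            k3u = a * (b * (v3 - vr) - u3)
            v4 = v + dt * k3v
            u4 = u + dt * k3u
            k4v = (k * (v4 - vr) * (v4 - vt) - u4 + I) / C
            k4u = a * (b * (v4 - vr) - u4)
            v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
            u_new = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)

            if drive.forced and forced_now.size:
                v_new[forced_now] = vpeak[forced_now] + 1.0

            spiked = v_new >= vpeak
            t_spike = (i + 1) * dt
            if spiked.any():
                ids = np.nonzero(spiked)[0]
                if not np.isfinite(v_new[ids]).all():
                    bad = ids[~np.isfinite(v_new[ids])][0]
                    raise IntegrationError(
                        f"non-finite dynamics at t={t_spike} ms, neuron {bad}")
                v_new[ids] = vmin[ids]
                u_new[ids] = u_new[ids] + d[ids]
                self._spike_ids.append(ids)
                self._spike_times.append(np.full(ids.size, t_spike))
                if self.plasticity_on and (in_presentation
                                           or not self.stdp_windows_only):
                    self.v, self.u = v_new, u_new
                    self._apply_stdp(ids, t_spike)
                self._ring[i % (self.delay_steps + 1)] = ids
            else:
                self._ring[i % (self.delay_steps + 1)] = np.empty(0, np.int64)
            if not np.isfinite(v_new).all():
                bad = int(np.nonzero(~np.isfinite(v_new))[0][0])
                raise IntegrationError(
                    f"non-finite dynamics at t={t_spike} ms, neuron {bad}")
            self.v, self.u = v_new, u_new
            self.step_index = i + 1

    def spike_record(self, seed: int | None = None) -> SpikeRecord:
        if self._spike_ids:
            ids = np.concatenate(self._spike_ids)
            times = np.concatenate(self._spike_times)
        else:
            ids = np.empty(0, np.int64)
            times = np.empty(0)
        return SpikeRecord(neuron_ids=ids, times=times, dt=self.dt,
                           duration=self.step_index * self.dt, seed=seed)


def run_simulation(
    network: NetworkInstance,
    drive: Drive | None = None,
    duration: float = 1000.0,
    dt: float = 0.2,
    rng_seed: int | None = None,
    plasticity_on: bool = False,
    background: np.ndarray | None = None,
    background_presentation: np.ndarray | None = None,
) -> tuple[SpikeRecord, NetworkInstance]:
    """Simulate ``duration`` ms and return the spike record and the network.

    The network's plastic weights are updated in place when plasticity is
    enabled.  Identical inputs produce bit-identical spike records.
    """
    sim = Simulator(network, dt=dt, plasticity_on=plasticity_on,
                    background=background,
                    background_presentation=background_presentation,
                    drive=drive)
    sim.run(int(round(duration / dt)))
    return sim.spike_record(seed=rng_seed), network
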