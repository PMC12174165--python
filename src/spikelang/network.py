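"""Reference time-driven network simulation kernel.

The kernel advances all populations on a fixed grid of resolution h (ms).
One step with current clock time t executes, in order:

1. *deliver* -- events scheduled to arrive at t are taken from the
   per-connection-group delay rings.  Plastic synapses are advanced lazily
   and their handlers run (see below); arriving weights either jump the
   target's convolution states or are queued for the target's own onReceive
   handlers, ordered by handler priority and source id.
2. *update* -- the update block runs; integrate_odes() advances the
   analytic part exactly by the propagator and the numeric part by RK4,
   with the analytic values seen by the numeric part frozen at the start of
   the step.
3. *conditions* -- onCondition handlers are evaluated in declaration order
   on the post-update state; emit_spike() marks the instance as spiking.
   Emitted spikes carry timestamp t + h.
4. *route* -- each spike is fanned out to the outgoing connection groups
   and scheduled to arrive at emission + delay; it is also scheduled as a
   postsynaptic notification on the incoming plastic connections of the
   spiking neuron, with the same per-connection delay.

Synapse instances are updated lazily, only when one of their events is
processed.  All synapse-side bookkeeping lives on the emission-side
timeline: an event processed at arrival time t with connection delay d is
anchored at the query time t - d, so a pre/post spike pair changes the
weight by exactly the closed-form kernel of the emission-time difference,
independent of the delay.  Because pre arrivals and post notifications are
conveyed with the same delay, the shifted timeline is monotone and every
trace value can be reconstructed analytically between events.  Co-generated
(paired) models replace the synapse's postsynaptic trace with an accessor
into the neuron's trace history, sampled on the grid and retained over a
window covering the largest delay.

Everything is vectorized over instances: a population's state is a dict of
(n,) arrays and a connection group's synapse state is a dict of (m,) arrays.
Time is kept as an integer step count; all times are in ms, potentials in
mV, currents in pA, conductances in nS, capacitances in pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import sympy as sp

from . import ast_nodes as A
from . import units as U
from .compiler import CompiledModel
from .diagnostics import error
from .evaluator import EvalEnv, eval_expr, exec_statements
from .odes import build_propagator, rk4_step


# -- devices ----------------------------------------------------------------

@dataclass
class StepCurrent:
    """DC stimulus on a continuous port: ``amplitude`` between start and stop."""

    amplitude: float  # in the port's declared unit (pA for current ports)
    start: float = 0.0  # ms
    stop: float = math.inf  # ms

    def value(self, t: float) -> float:
        return self.amplitude if self.start <= t < self.stop else 0.0


@dataclass
class PoissonInput:
    """Independent Poisson spike drive onto a spike port of every instance."""

    rate: float  # spikes/s per target
    weight: float = 1.0
    start: float = 0.0
    stop: float = math.inf


@dataclass
class SpikeTrainInput:
    """Explicit input spike times (ms, arrival semantics) onto a spike port.

    Arrival times are rounded *up* to the next grid point, mirroring how a
    time-driven simulation processes a spike at the start of the step that
    follows its true occurrence.
    """

    times: Sequence[float]
    weight: float = 1.0


@dataclass
class FixedIndegree:
    """Each target draws k distinct sources (autapses allowed, multapses not)."""

    k: int
    targets: Optional[np.ndarray] = None  # subset of target ids; default all


# -- recording --------------------------------------------------------------

class Recording:
    """Spike trains, sampled state variables, and sampled weights."""

    def __init__(self):
        self.spike_times: dict[str, list] = {}
        self.spike_ids: dict[str, list] = {}
        self.state_times: dict[str, list] = {}
        self.state_samples: dict[tuple[str, str], list] = {}
        self.weight_times: list = []
        self.weight_samples: dict[str, list] = {}

    def spikes(self, pop_name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times ms, neuron ids), time-ordered."""
        times = self.spike_times.get(pop_name, [])
        ids = self.spike_ids.get(pop_name, [])
        if not times:
            return np.empty(0), np.empty(0, dtype=int)
        return (np.concatenate([np.asarray(t) for t in times]),
                np.concatenate([np.asarray(i) for i in ids]))

    def state(self, pop_name: str, var: str) -> tuple[np.ndarray, np.ndarray]:
        """(times ms, samples with shape (n_samples, n))."""
        t = np.asarray(self.state_times.get(pop_name, []))
        arr = np.asarray(self.state_samples.get((pop_name, var), []))
        return t, arr

    def weights(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.weight_times),
                np.asarray(self.weight_samples.get(label, [])))

    # -- plain-text export ---------------------------------------------------

    def spikes_text(self, pop_name: str) -> str:
        """Two-column text: neuron id, spike time (ms)."""
        times, ids = self.spikes(pop_name)
        lines = [f"{int(i)}\t{t:.6f}" for i, t in zip(ids, times)]
        return "\n".join(lines) + ("\n" if lines else "")

    def state_text(self, pop_name: str, variables: list[str]) -> str:
        """Delimited text with a header row; one line per sample time."""
        t, _ = self.state(pop_name, variables[0])
        cols = [self.state(pop_name, v)[1] for v in variables]
        header = "time_ms\t" + "\t".join(
            f"{v}[{j}]" for v, c in zip(variables, cols) for j in range(c.shape[1]))
        lines = [header]
        for i, ti in enumerate(t):
            row = [f"{ti:.6f}"]
            for c in cols:
                row.extend(f"{x:.17g}" for x in c[i])
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


# -- populations ------------------------------------------------------------

class Population:
    def __init__(self, net: "Network", model: CompiledModel, n: int,
                 overrides: Optional[dict] = None, name: Optional[str] = None):
        self.net = net
        self.model = model
        self.n = n
        self.name = name or f"{model.name}#{len(net.populations)}"
        self.params: dict[str, object] = dict(model.parameter_defaults)
        if overrides:
            self._apply_overrides(overrides)

        self.state: dict[str, np.ndarray] = {}
        self._init_state()

        self._scalar_params = {k: v for k, v in self.params.items()
                               if np.ndim(v) == 0}
        self.propagator = None
        if model.plan.analytic_states:
            self._check_scalar(model.plan.matrix.free_symbols, "analytic dynamics")
            self.propagator = build_propagator(
                model.plan.matrix, net.h, self._scalar_params, model.plan.offset)
        self.jump_vectors: dict[str, Optional[np.ndarray]] = {}
        for port in model.spike_port_names:
            vec = None
            if model.system.spike_jumps.get(port):
                for j in model.system.spike_jumps[port].values():
                    self._check_scalar(j.free_symbols, "spike jumps")
                vec = model.jump_vector(port, self._scalar_params)
            self.jump_vectors[port] = vec

        self.handlers_by_port: dict[str, list[A.OnReceive]] = {}
        for h in model.handlers:
            self.handlers_by_port.setdefault(h.port, []).append(h)

        # input plumbing
        self.port_accum = {p: np.zeros(n) for p in model.spike_port_names}
        self.port_events: dict[str, list] = {p: [] for p in model.spike_port_names}
        self.cont_values = {p: 0.0 for p in model.continuous_port_names}
        self.current_devices: list[tuple[str, StepCurrent]] = []
        self.poisson_devices: list[tuple[str, PoissonInput]] = []
        self.train_devices: list[tuple[str, SpikeTrainInput, dict]] = []

        self.emitted = np.zeros(n, dtype=bool)
        self.out_groups: list["ConnectionGroup"] = []
        self.in_groups: list["ConnectionGroup"] = []

        # grid-sampled history of moved (co-generated) trace states,
        # retained over a ring covering the largest incoming delay
        self.trace_hist: dict[str, np.ndarray] = {}
        self._hist_len = 0

        self.record_spikes = False
        self.record_vars: list[str] = []
        self.record_interval = 1

    # -- construction helpers ------------------------------------------------

    def _check_scalar(self, symbols, what: str) -> None:
        for s in symbols:
            v = self.params.get(str(s))
            if v is not None and np.ndim(v) != 0:
                raise error("per-instance-param",
                            f"parameter {s} enters the {what} and cannot be "
                            "overridden per instance")

    def _apply_overrides(self, overrides: dict) -> None:
        scope = self.model.scope
        for name, value in overrides.items():
            sym = scope.lookup(name)
            if sym is None or sym.kind not in ("parameter", "internal"):
                raise error("unknown-parameter",
                            f"{name!r} is not a parameter of model "
                            f"{self.model.name!r}")
            factor = 1.0
            if isinstance(value, tuple):
                magnitude, unit_text = value
                given = U.parse_unit(unit_text)
                if sym.type is None or sym.type.kind != "quantity":
                    raise U.UnitError(
                        f"parameter {name!r} is {sym.type}, not a quantity")
                factor = U.conversion_factor(given, sym.type.quantity)
                value = magnitude
            arr = np.asarray(value, dtype=float) * factor
            self.params[name] = float(arr) if arr.ndim == 0 else arr

    def _init_state(self) -> None:
        model = self.model
        n = self.n
        env_values: dict = dict(self.params)
        env = EvalEnv(env_values, n=n, rng=self.net.rng)
        decls = {d.name: d for d in (model.ast.state.declarations
                                     if model.ast.state else [])}
        for name in model.state_names:
            d = decls.get(name)
            if d is None or d.initializer is None:
                v = np.zeros(n)
            else:
                raw = eval_expr(d.initializer, env)
                if d.init_factor != 1.0:
                    raw = raw * d.init_factor
                size = None
                if d.size is not None:
                    size = (d.size if isinstance(d.size, int)
                            else int(np.asarray(self.params[d.size]).flat[0]))
                shape = (n,) if size is None else (n, size)
                v = np.broadcast_to(np.asarray(raw, dtype=float), shape).copy()
            self.state[name] = v
            env_values[name] = v

    def _prepare_history(self) -> None:
        """(Re)build the trace-history rings before a simulation run."""
        if not self.model.moved_traces:
            return
        max_d = max((int(g.delay_steps.max()) for g in self.in_groups
                     if g.synapse is not None), default=1)
        need = max_d + 2
        if need > self._hist_len:
            for mt in self.model.moved_traces:
                ring = np.empty((need, self.n))
                ring[:] = self.state[mt.state]
                self.trace_hist[mt.state] = ring
            self._hist_len = need

    def _record_history(self, stamp_step: int) -> None:
        for name, ring in self.trace_hist.items():
            ring[stamp_step % self._hist_len] = self.state[name]

    def trace_at(self, state: str, ids: np.ndarray,
                 q_steps: np.ndarray) -> np.ndarray:
        """Moved-trace accessor: grid value at query step, per target id."""
        ring = self.trace_hist[state]
        return ring[q_steps % self._hist_len, ids]

    # -- per-step work --------------------------------------------------------

    def _apply_continuous(self, t: float) -> None:
        for port in self.cont_values:
            total = 0.0
            for p, dev in self.current_devices:
                if p == port:
                    total = total + dev.value(t)
            self.cont_values[port] = total

    def _deposit(self, port: str, targets: np.ndarray, weights) -> None:
        """Accumulate arriving weights; queue events for handler ports."""
        vec = self.jump_vectors.get(port)
        if vec is not None:
            np.add.at(self.port_accum[port], targets, weights)
        if self.handlers_by_port.get(port):
            w = np.broadcast_to(np.asarray(weights, dtype=float), targets.shape)
            self.port_events[port].append((targets, w.copy()))

    def _apply_jumps(self) -> None:
        for port, vec in self.jump_vectors.items():
            if vec is None:
                continue
            acc = self.port_accum[port]
            if not acc.any():
                continue
            for i, coeff in enumerate(vec):
                if coeff != 0.0:
                    self.state[self.model.system.state_names[i]] += coeff * acc
        for port in self.port_accum:
            self.port_accum[port][:] = 0.0

    def _run_port_handlers(self, t: float) -> None:
        """Per-event execution of neuron-side onReceive handlers."""
        if not any(self.port_events[p] for p in self.port_events):
            return
        # order: priority (desc), then port declaration order
        port_order = {p: i for i, p in enumerate(self.model.spike_port_names)}
        jobs = []
        for port, batches in self.port_events.items():
            handlers = self.handlers_by_port.get(port)
            if not handlers or not batches:
                continue
            prio = max((h.priority or 0) for h in handlers)
            jobs.append((-prio, port_order[port], port, batches))
        jobs.sort(key=lambda j: (j[0], j[1]))
        mod = self.model.exec_module
        for _, _, port, batches in jobs:
            for targets, weights in batches:
                for j, handler in enumerate(self.handlers_by_port[port]):
                    fn = (mod.HANDLERS[port][j] if mod is not None else None)
                    for tgt, w in zip(targets, weights):
                        mask = np.zeros(self.n, dtype=bool)
                        mask[tgt] = True
                        env = self._make_env(t)
                        env.values[port] = float(w)
                        if fn is not None:
                            fn(env, mask)
                        else:
                            exec_statements(handler.statements, env, mask)
        for port in self.port_events:
            self.port_events[port].clear()

    def _make_env(self, t: float) -> EvalEnv:
        values: dict = {}
        values.update(self.params)
        values.update(self.cont_values)
        values.update(self.state)
        return EvalEnv(values, n=self.n, rng=self.net.rng, t=t,
                       emit_spike=self._emit_spike,
                       integrate_odes=lambda names: self._integrate(t, names),
                       functions=self.model.user_functions)

    def _emit_spike(self, mask) -> None:
        if mask is None:
            self.emitted[:] = True
        else:
            self.emitted |= mask

    def _integrate(self, t: float, names: list[str]) -> None:
        """Advance the ODE states by one grid step h."""
        model = self.model
        h = self.net.h
        if names:
            self._integrate_subset(t, names, h)
            return
        numeric = model.plan.numeric_states
        analytic = model.plan.analytic_states
        analytic_vals = [self.state[s] for s in analytic]
        if numeric:
            y0 = np.stack([self.state[s] for s in numeric])
            frozen = [np.array(v, copy=True) for v in analytic_vals]
            plain = [self.state[s] for s in model.plain_states]

            def f(tk, y):
                derivs = model.numeric_rhs(tk, list(y), frozen, plain,
                                           self.params, self.cont_values)
                return np.stack([np.broadcast_to(np.asarray(d, dtype=float),
                                                 (self.n,)) for d in derivs])

            y1 = rk4_step(f, t, y0, h, self.net.substeps)
            for i, s in enumerate(numeric):
                self.state[s][...] = y1[i]
        if analytic:
            y = np.stack(analytic_vals)
            p = self.propagator
            y1 = p.matrix @ y + p.offset[:, None]
            for i, s in enumerate(analytic):
                self.state[s][...] = y1[i]

    def _integrate_subset(self, t: float, names: list[str], h: float) -> None:
        """integrate_odes(x, y, ...): advance only the listed states (RK4),
        holding every other state frozen over the step."""
        model = self.model
        missing = [s for s in names if s not in model.system.derivatives]
        if missing:
            raise error("integrate-odes-arg",
                        f"no differential equation for {missing[0]!r}")
        others = [s for s in model.system.state_names if s not in names]
        others += model.plain_states
        args = ([sp.Symbol("t")] + [sp.Symbol(s) for s in names]
                + [sp.Symbol(s) for s in others]
                + [sp.Symbol(p) for p in model.parameter_names]
                + [sp.Symbol(c) for c in model.continuous_port_names])
        fn = sp.lambdify(args, [model.system.derivatives[s] for s in names],
                         modules="numpy")
        frozen = [np.array(self.state[s], copy=True) for s in others]
        pargs = [self.params[p] for p in model.parameter_names]
        cargs = [self.cont_values[c] for c in model.continuous_port_names]

        def f(tk, y):
            derivs = fn(tk, *list(y), *frozen, *pargs, *cargs)
            return np.stack([np.broadcast_to(np.asarray(d, dtype=float),
                                             (self.n,)) for d in derivs])

        y0 = np.stack([self.state[s] for s in names])
        y1 = rk4_step(f, t, y0, h, self.net.substeps)
        for i, s in enumerate(names):
            self.state[s][...] = y1[i]

    def _run_update(self, t: float) -> None:
        stmts = self.model.update_statements
        if not stmts:
            return
        env = self._make_env(t)
        mod = self.model.exec_module
        if mod is not None and mod.UPDATE is not None:
            mod.UPDATE(env)
        else:
            exec_statements(stmts, env)
        self._write_back(env)

    def _run_conditions(self, t: float) -> None:
        self.emitted[:] = False
        mod = self.model.exec_module
        if mod is not None:
            for cond_fn, body_fn in mod.CONDITIONS:
                env = self._make_env(t)
                c = cond_fn(env)
                mask = np.broadcast_to(np.asarray(c, dtype=bool),
                                       (self.n,)).copy()
                if mask.any():
                    body_fn(env, mask)
                    self._write_back(env)
            return
        for cond in self.model.conditions:
            env = self._make_env(t)
            c = eval_expr(cond.condition, env)
            mask = np.broadcast_to(np.asarray(c, dtype=bool), (self.n,)).copy()
            if mask.any():
                exec_statements(cond.statements, env, mask)
                self._write_back(env)

    def _write_back(self, env: EvalEnv) -> None:
        for s in self.state:
            v = env.values.get(s)
            if v is not None and v is not self.state[s]:
                self.state[s][...] = v

    def _check_finite(self, t: float) -> None:
        for s in self.model.plan.numeric_states:
            arr = self.state[s]
            if not np.all(np.isfinite(arr)):
                bad = int(np.nonzero(~np.isfinite(arr))[0][0])
                raise error("numeric-divergence",
                            f"state {s!r} of {self.name} neuron {bad} became "
                            f"non-finite at t={t:.3f} ms")


# -- connections ------------------------------------------------------------

class ConnectionGroup:
    """A batch of edges sharing source/target populations and synapse model.

    Plastic synapses live on the emission-side timeline: an event processed
    at arrival step s with per-connection delay d is anchored at coordinate
    (s - d) * h.  Pre arrivals and postsynaptic notifications both travel
    with the connection delay, so anchoring times are monotone per synapse.
    """

    def __init__(self, net: "Network", source: Population, target: Population,
                 src: np.ndarray, tgt: np.ndarray, weight, delay,
                 synapse: Optional[CompiledModel], receptor: Optional[str],
                 pre_port: Optional[str], post_ports: Optional[list[str]],
                 label: Optional[str] = None):
        self.net = net
        self.source = source
        self.target = target
        self.src = np.asarray(src, dtype=np.int64)
        self.tgt = np.asarray(tgt, dtype=np.int64)
        m = len(self.src)
        self.m = m
        self.weight = np.broadcast_to(np.asarray(weight, dtype=float), (m,)).copy()
        delay_arr = np.broadcast_to(np.asarray(delay, dtype=float), (m,))
        steps = np.round(delay_arr / net.h).astype(np.int64)
        if np.any(steps < 1) or np.any(np.abs(steps * net.h - delay_arr) > 1e-9):
            raise error("bad-delay",
                        "delays must be positive multiples of the resolution h")
        self.delay_steps = steps
        self.label = label or f"{source.name}->{target.name}#{len(net.groups)}"

        if receptor is None:
            if not target.model.spike_port_names:
                raise error("no-port", f"target {target.name} has no spike port")
            receptor = target.model.spike_port_names[0]
        self.receptor = receptor

        self.synapse = synapse
        self.syn_state: dict[str, np.ndarray] = {}
        self.last_anchor = np.zeros(m)  # emission-side coordinate
        self.pre_port = pre_port
        self.post_ports = list(post_ports or [])
        self._pre_handlers: list[A.OnReceive] = []
        self._post_handlers: list[A.OnReceive] = []
        self._decay: list[tuple[str, float]] = []
        if synapse is not None:
            self._setup_synapse()

        # by-source CSR for routing presynaptic spikes
        order = np.argsort(self.src, kind="stable")
        self.by_src_order = order
        self.by_src_indptr = np.searchsorted(
            self.src[order], np.arange(source.n + 1))
        # by-target CSR for postsynaptic notification
        self.by_tgt_order = None
        if self._post_handlers:
            order_t = np.argsort(self.tgt, kind="stable")
            self.by_tgt_order = order_t
            self.by_tgt_indptr = np.searchsorted(
                self.tgt[order_t], np.arange(target.n + 1))

        self.ring_len = int(self.delay_steps.max()) + 2
        uniq = np.unique(self.delay_steps)
        self._uniform_delay = int(uniq[0]) if len(uniq) == 1 else None
        self.pending_pre: list[list[np.ndarray]] = [[] for _ in range(self.ring_len)]
        self.pending_post: list[list[np.ndarray]] = [[] for _ in range(self.ring_len)]

    def _setup_synapse(self) -> None:
        syn = self.synapse
        if self.pre_port is None and syn.spike_port_names:
            non_post = [p for p in syn.spike_port_names if p not in self.post_ports]
            self.pre_port = non_post[0] if non_post else syn.spike_port_names[0]
        decls = {d.name: d for d in (syn.ast.state.declarations
                                     if syn.ast.state else [])}
        for name in syn.state_names:
            init = syn.system.initial_values.get(name)
            if init is not None and not init.free_symbols:
                v = float(init)
            else:
                d = decls.get(name)
                if d is not None and d.initializer is not None:
                    env = EvalEnv(dict(syn.parameter_defaults), n=1,
                                  rng=self.net.rng)
                    v = float(np.asarray(eval_expr(d.initializer, env)).flat[0]
                              * d.init_factor)
                else:
                    v = 0.0
            self.syn_state[name] = np.full(self.m, v)
        # the weight given to connect() seeds the synapse's weight state
        if "w" in self.syn_state:
            self.syn_state["w"][...] = self.weight
        for h in self.synapse.handlers:  # already priority-sorted
            if h.port == self.pre_port:
                self._pre_handlers.append(h)
            elif h.port in self.post_ports:
                self._post_handlers.append(h)
        rates = syn.decay_rates
        if rates is None and syn.plan.analytic_states:
            raise error("synapse-dynamics",
                        "lazy synapse updates need decoupled exponential-decay "
                        "trace dynamics")
        if syn.plan.numeric_states:
            raise error("synapse-dynamics",
                        "synapse models with nonlinear continuous dynamics are "
                        "not supported by the lazy update scheme")
        if rates:
            subs = {sp.Symbol(k): v for k, v in syn.parameter_defaults.items()}
            for s, rate in rates.items():
                self._decay.append((s, float(rate.subs(subs).evalf())))

    # -- scheduling ----------------------------------------------------------

    def schedule_pre(self, step: int, spiking_sources: np.ndarray) -> None:
        """Queue pre-spike deliveries; emission stamp is (step+1)*h."""
        parts = [self.by_src_order[self.by_src_indptr[s]:self.by_src_indptr[s + 1]]
                 for s in spiking_sources]
        idxs = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        if idxs.size == 0:
            return
        self._enqueue(self.pending_pre, step, idxs)

    def schedule_post(self, step: int, spiking_targets: np.ndarray) -> None:
        """Queue postsynaptic notifications for spiking target neurons."""
        if self.by_tgt_order is None:
            return
        parts = [self.by_tgt_order[self.by_tgt_indptr[s]:self.by_tgt_indptr[s + 1]]
                 for s in spiking_targets]
        idxs = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        if idxs.size == 0:
            return
        self._enqueue(self.pending_post, step, idxs)

    def _enqueue(self, pending, step: int, idxs: np.ndarray) -> None:
        if self._uniform_delay is not None:
            slot = (step + 1 + self._uniform_delay) % self.ring_len
            pending[slot].append(idxs)
            return
        delays = self.delay_steps[idxs]
        for d in np.unique(delays):
            sel = idxs[delays == d]
            slot = (step + 1 + int(d)) % self.ring_len
            pending[slot].append(sel)

    # -- event processing ----------------------------------------------------

    def _advance_lazy(self, idxs: np.ndarray, anchors: np.ndarray,
                      local: Optional[dict] = None) -> None:
        """Decay the trace states over the elapsed anchor time; with
        ``local`` given, operate on pre-gathered per-batch arrays."""
        dt = anchors - self.last_anchor[idxs]
        if local is None:
            for s, rate in self._decay:
                self.syn_state[s][idxs] *= np.exp(-rate * dt)
        else:
            for s, rate in self._decay:
                local[s] *= np.exp(-rate * dt)
        self.last_anchor[idxs] = anchors

    def _syn_env(self, idxs: np.ndarray, t_anchor, step: int,
                 delivered: Optional[list] = None,
                 local: Optional[dict] = None):
        values: dict = dict(self.synapse.parameter_defaults)
        if local is None:
            local = {s: self.syn_state[s][idxs] for s in self.syn_state}
        values.update(local)
        nb = len(idxs)

        def deliver(wvals, mask):
            w = np.broadcast_to(np.asarray(wvals, dtype=float), (nb,))
            if mask is not None:
                w = np.where(mask, w, 0.0)
            delivered.append(np.array(w, copy=True))

        accessors = {}
        tgt_ids = self.tgt[idxs]
        q_steps = step - self.delay_steps[idxs]
        for mt in self.target.model.moved_traces:
            accessors[mt.accessor] = (
                lambda mask, _s=mt.state, _ids=tgt_ids, _q=q_steps:
                self.target.trace_at(_s, _ids, _q))
        env = EvalEnv(values, n=nb, rng=self.net.rng, t=t_anchor,
                      deliver_spike=deliver if delivered is not None else None,
                      accessors=accessors,
                      functions=self.synapse.user_functions)
        return env, local

    def deliver(self, step: int, t: float) -> None:
        """Process events whose arrival step is now.

        Post notifications and pre arrivals landing on the same step are
        ordered by their handlers' priorities (model-declared); ties favor
        the postsynaptic handler.
        """
        slot = step % self.ring_len
        pre_batches = self.pending_pre[slot]
        post_batches = self.pending_post[slot]
        if not pre_batches and not post_batches:
            return
        self.pending_pre[slot] = []
        self.pending_post[slot] = []
        if self.synapse is None:
            if pre_batches:
                idxs = (np.concatenate(pre_batches) if len(pre_batches) > 1
                        else pre_batches[0])
                self.target._deposit(self.receptor, self.tgt[idxs],
                                     self.weight[idxs])
            return
        pre_prio = max(((h.priority or 0) for h in self._pre_handlers), default=0)
        post_prio = max(((h.priority or 0) for h in self._post_handlers), default=0)
        jobs = [(1, post_batches), (0, pre_batches)]
        if pre_prio > post_prio:
            jobs.reverse()
        mod = self.synapse.exec_module
        for is_post, batches in jobs:
            if not batches:
                continue
            idxs = np.concatenate(batches) if len(batches) > 1 else batches[0]
            anchors = t - self.delay_steps[idxs] * self.net.h
            local = {s: self.syn_state[s][idxs] for s in self.syn_state}
            self._advance_lazy(idxs, anchors, local)
            handlers = self._post_handlers if is_post else self._pre_handlers
            delivered: list = [] if not is_post else None
            env, local = self._syn_env(idxs, anchors, step, delivered, local)
            port_counters: dict[str, int] = {}
            for h in handlers:
                env.values[h.port] = 1.0
                j = port_counters.get(h.port, 0)
                port_counters[h.port] = j + 1
                if mod is not None:
                    mod.HANDLERS[h.port][j](env)
                else:
                    exec_statements(h.statements, env)
            for s in local:
                self.syn_state[s][idxs] = env.values[s]
            if delivered:
                for w in delivered:
                    self.target._deposit(self.receptor, self.tgt[idxs], w)

    def flush(self) -> None:
        """Drain pending events and advance all traces to the current time.

        Weights are unaffected by the decay itself, but pending pre/post
        events still in flight are processed at their scheduled anchors.
        """
        net = self.net
        horizon = net.step + self.ring_len
        for s in range(net.step, horizon):
            self.deliver(s, s * net.h)
        if self.synapse is not None:
            anchors = np.full(self.m, net.time) - self.delay_steps * net.h
            np.maximum(anchors, self.last_anchor, out=anchors)
            self._advance_lazy(np.arange(self.m), anchors)

    @property
    def weights(self) -> np.ndarray:
        """Current synaptic weights (the synapse's w state when plastic)."""
        if self.synapse is not None and "w" in self.syn_state:
            return self.syn_state["w"]
        return self.weight


# -- the network ------------------------------------------------------------

class Network:
    """Populations + connections + clock; owns the seeded RNG."""

    def __init__(self, h: float = 0.1, seed: int = 1, substeps: int = 1):
        if h <= 0:
            raise error("bad-resolution", "resolution h must be positive")
        self.h = h
        self.seed = seed
        self.substeps = substeps
        self.rng = np.random.default_rng(seed)
        self.populations: list[Population] = []
        self.groups: list[ConnectionGroup] = []
        self.step = 0
        self.recording = Recording()
        self._record_weight_groups: list[tuple[ConnectionGroup, np.ndarray]] = []
        self._weight_interval = 1

    @property
    def time(self) -> float:
        return self.step * self.h

    # -- construction --------------------------------------------------------

    def create(self, model: CompiledModel, n: int = 1,
               overrides: Optional[dict] = None,
               name: Optional[str] = None) -> Population:
        pop = Population(self, model, n, overrides, name)
        self.populations.append(pop)
        return pop

    def connect(self, source: Population, target: Population,
                rule: Union[FixedIndegree, Sequence, None] = None,
                synapse: Optional[CompiledModel] = None,
                weight: float = 1.0, delay: float = 1.0,
                receptor: Optional[str] = None,
                pre_port: Optional[str] = None,
                post_ports: Optional[list[str]] = None,
                label: Optional[str] = None) -> ConnectionGroup:
        """Create connections; ``rule`` is explicit (src, tgt) pairs or
        :class:`FixedIndegree`."""
        if isinstance(rule, FixedIndegree):
            if rule.k > source.n:
                raise error("indegree",
                            f"in-degree {rule.k} exceeds source pool size "
                            f"{source.n}")
            targets = (np.asarray(rule.targets, dtype=np.int64)
                       if rule.targets is not None
                       else np.arange(target.n, dtype=np.int64))
            src = np.empty(rule.k * len(targets), dtype=np.int64)
            tgt = np.empty_like(src)
            for j, tg in enumerate(targets):
                src[j * rule.k:(j + 1) * rule.k] = self.rng.choice(
                    source.n, size=rule.k, replace=False)
                tgt[j * rule.k:(j + 1) * rule.k] = tg
        elif rule is None:
            raise error("no-rule", "a connection rule or explicit pairs required")
        else:
            pairs = np.asarray(rule, dtype=np.int64)
            if pairs.ndim == 1:
                pairs = pairs.reshape(1, 2)
            src, tgt = pairs[:, 0], pairs[:, 1]
        group = ConnectionGroup(self, source, target, src, tgt, weight, delay,
                                synapse, receptor, pre_port, post_ports, label)
        self.groups.append(group)
        source.out_groups.append(group)
        target.in_groups.append(group)
        return group

    # -- devices -------------------------------------------------------------

    def attach_current(self, pop: Population, port: str, device: StepCurrent):
        if port not in pop.cont_values:
            raise error("no-port", f"{pop.name} has no continuous port {port!r}")
        pop.current_devices.append((port, device))

    def attach_poisson(self, pop: Population, port: str, device: PoissonInput):
        if port not in pop.port_accum:
            raise error("no-port", f"{pop.name} has no spike port {port!r}")
        pop.poisson_devices.append((port, device))

    def attach_spike_train(self, pop: Population, port: str,
                           device: SpikeTrainInput):
        if port not in pop.port_accum:
            raise error("no-port", f"{pop.name} has no spike port {port!r}")
        arrivals: dict[int, int] = {}
        for tm in device.times:
            stepno = int(math.ceil(tm / self.h - 1e-9))
            arrivals[stepno] = arrivals.get(stepno, 0) + 1
        pop.train_devices.append((port, device, arrivals))

    # -- recording -----------------------------------------------------------

    def record(self, pop: Population, variables: Optional[list[str]] = None,
               interval: Optional[float] = None) -> None:
        pop.record_spikes = True
        if variables:
            pop.record_vars = list(variables)
            pop.record_interval = (int(round(interval / self.h))
                                   if interval else 1)

    def record_weights(self, group: ConnectionGroup,
                       indices: Optional[np.ndarray] = None,
                       interval: Optional[float] = None) -> None:
        idx = (np.asarray(indices, dtype=np.int64) if indices is not None
               else np.arange(group.m))
        self._record_weight_groups.append((group, idx))
        if interval:
            self._weight_interval = int(round(interval / self.h))

    # -- simulation ----------------------------------------------------------

    def simulate(self, duration: float) -> Recording:
        """Advance the network by ``duration`` ms (a multiple of h)."""
        n_steps = int(round(duration / self.h))
        if abs(n_steps * self.h - duration) > 1e-9:
            raise error("bad-duration",
                        "simulation duration must be a multiple of the "
                        "resolution h")
        rec = self.recording
        for pop in self.populations:
            pop._prepare_history()
            if pop.record_spikes:
                rec.spike_times.setdefault(pop.name, [])
                rec.spike_ids.setdefault(pop.name, [])
                rec.state_times.setdefault(pop.name, [])
                for v in pop.record_vars:
                    rec.state_samples.setdefault((pop.name, v), [])

        for _ in range(n_steps):
            t = self.step * self.h
            t_spike = t + self.h

            # phase 0: continuous inputs and stochastic devices
            for pop in self.populations:
                pop._apply_continuous(t)
                for port, dev in pop.poisson_devices:
                    if dev.start <= t < dev.stop and np.any(np.asarray(dev.rate) > 0):
                        lam = np.asarray(dev.rate) * self.h * 1e-3
                        counts = self.rng.poisson(lam, pop.n)
                        if counts.any():
                            nz = np.nonzero(counts)[0]
                            pop._deposit(port, nz, dev.weight * counts[nz])
                for port, dev, arrivals in pop.train_devices:
                    cnt = arrivals.get(self.step, 0)
                    if cnt:
                        pop._deposit(port, np.arange(pop.n),
                                     np.full(pop.n, dev.weight * cnt))

            # phase 1: deliver (synapse events first, then jumps/handlers)
            for group in self.groups:
                group.deliver(self.step, t)
            for pop in self.populations:
                pop._apply_jumps()
                pop._run_port_handlers(t)

            # phase 2: update (free-flight integration)
            for pop in self.populations:
                pop._run_update(t)
                pop._check_finite(t)

            # phase 3: conditions; emitted spikes carry stamp t + h
            for pop in self.populations:
                pop._run_conditions(t)

            # phase 4: record + route
            for pop in self.populations:
                if pop.emitted.any():
                    ids = np.nonzero(pop.emitted)[0]
                    if pop.record_spikes:
                        rec.spike_times[pop.name].append(
                            np.full(ids.size, t_spike))
                        rec.spike_ids[pop.name].append(ids.copy())
                    for group in pop.out_groups:
                        group.schedule_pre(self.step, ids)
                    for group in pop.in_groups:
                        group.schedule_post(self.step, ids)
                pop._record_history(self.step + 1)

            self.step += 1

            # sampling (state corresponds to time t + h after the update)
            for pop in self.populations:
                if pop.record_vars and self.step % pop.record_interval == 0:
                    rec.state_times[pop.name].append(self.step * self.h)
                    for v in pop.record_vars:
                        rec.state_samples[(pop.name, v)].append(
                            np.array(pop.state[v], copy=True))
            if self._record_weight_groups and \
                    self.step % self._weight_interval == 0:
                rec.weight_times.append(self.step * self.h)
                for group, idx in self._record_weight_groups:
                    rec.weight_samples.setdefault(group.label, []).append(
                        np.array(group.weights[idx], copy=True))
        return rec

    def finalize(self) -> None:
        """Process in-flight synapse events and advance traces to now.

        Weights deposited by flushed events are discarded (their targets are
        never integrated past the current time).
        """
        for group in self.groups:
            group.flush()
        for pop in self.populations:
            for port in pop.port_accum:
                pop.port_accum[port][:] = 0.0
                pop.port_events[port].clear()
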