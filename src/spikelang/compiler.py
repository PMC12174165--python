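"""Compilation: validated AST -> executable model description.

A :class:`CompiledModel` bundles everything the simulation kernel needs: the
lowered first-order system, the solver plan (exact propagator part vs. RK4
part), evaluated parameter defaults, the event handlers sorted by priority,
and lazily-built numpy callables for the numeric right-hand side and the
per-port jump vectors.  The compiled artifact (lowered system + plan +
printed model) serializes to JSON for inspection and for the ``generate``
command.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Union

import numpy as np
import sympy as sp

from . import ast_nodes as A
from .diagnostics import Diagnostic, ModelError, has_errors
from .evaluator import EvalEnv, eval_expr
from .odes import (FirstOrderSystem, Propagator, SolverPlan, build_propagator,
                   classify, lower_model)
from .parser import parse_model
from .printer import print_model
from .symbols import INTERNAL, PARAMETER, STATE, SymbolTable
from .validation import ModelChecker

_LAMBDIFY_MODULES = [{"Min": np.minimum, "Max": np.maximum}, "numpy", "scipy"]


@dataclass
class MovedTrace:
    """Bookkeeping for a state moved into the neuron by co-generation."""

    state: str           # name of the moved state inside the neuron
    tau_param: str       # decay time-constant parameter (neuron side)
    jump: float          # increment per own (postsynaptic) spike
    accessor: str        # accessor function name used by the synapse


@dataclass
class CompiledModel:
    ast: A.Model
    scope: SymbolTable
    diagnostics: list[Diagnostic]
    system: FirstOrderSystem
    plan: SolverPlan
    parameter_names: list[str]
    parameter_defaults: dict[str, float]
    state_names: list[str]              # ODE states first, then plain states
    plain_states: list[str]             # states without differential equations
    spike_port_names: list[str]
    continuous_port_names: list[str]
    handlers: list[A.OnReceive]         # sorted: higher priority first
    conditions: list[A.OnCondition]
    update_statements: list[A.Statement]
    moved_traces: list[MovedTrace] = field(default_factory=list)
    moved_symbols: set[str] = field(default_factory=set)
    # optional generated-code module (see spikelang.codegen); when attached,
    # the kernel executes it instead of interpreting the AST
    exec_module: object = None

    @property
    def name(self) -> str:
        return self.ast.name

    @property
    def is_spiking(self) -> bool:
        out = self.ast.output
        return out is not None and out.kind == "spike"

    @cached_property
    def is_synapse(self) -> bool:
        """A model that forwards events with deliver_spike() acts as a synapse."""
        for h in self.handlers:
            for node in h.statements:
                for sub in A.walk(node):
                    if isinstance(sub, A.FunctionCall) and sub.name == "deliver_spike":
                        return True
        return False

    # -- numeric plumbing ----------------------------------------------------

    @cached_property
    def _rhs_compiled(self):
        """Lambdified derivatives of the numeric part.

        Signature: f(t, *numeric, *analytic, *params, *continuous_ports)
        returning a list of derivative arrays, one per numeric state.
        """
        num = self.plan.numeric_states
        if not num:
            return None
        args = ([sp.Symbol("t")] + [sp.Symbol(s) for s in num]
                + [sp.Symbol(s) for s in self.plan.analytic_states]
                + [sp.Symbol(s) for s in self.plain_states]
                + [sp.Symbol(p) for p in self.parameter_names]
                + [sp.Symbol(c) for c in self.continuous_port_names])
        exprs = [self.system.derivatives[s] for s in num]
        return sp.lambdify(args, exprs, modules=_LAMBDIFY_MODULES)

    def numeric_rhs(self, t: float, numeric_values: list, analytic_values: list,
                    plain_values: list, params: dict, port_values: dict) -> list:
        f = self._rhs_compiled
        param_args = [params[p] for p in self.parameter_names]
        port_args = [port_values[c] for c in self.continuous_port_names]
        return f(t, *numeric_values, *analytic_values, *plain_values,
                 *param_args, *port_args)

    def propagator(self, params: dict[str, float], h: float) -> Optional[Propagator]:
        if not self.plan.analytic_states:
            return None
        return build_propagator(self.plan.matrix, h, params, self.plan.offset)

    def jump_vector(self, port: str, params: dict[str, float]) -> Optional[np.ndarray]:
        """Per-unit-weight state increments for spikes arriving at ``port``."""
        jumps = self.system.spike_jumps.get(port)
        if not jumps:
            return None
        subs = {sp.Symbol(k): v for k, v in params.items()}
        vec = np.zeros(len(self.system.state_names))
        for i, name in enumerate(self.system.state_names):
            if name in jumps:
                vec[i] = float(jumps[name].subs(subs).evalf())
        return vec

    @cached_property
    def decay_rates(self) -> Optional[dict[str, sp.Expr]]:
        """For decoupled analytic states x' = -lambda x: state -> rate lambda.

        Returns None unless the analytic matrix is diagonal and homogeneous,
        in which case each analytic state advances independently as an
        exponential decay over an arbitrary elapsed time -- the form needed
        for lazy, event-driven synapse updates.
        """
        m = self.plan.matrix
        if m is None:
            return None
        n = m.shape[0]
        if self.plan.offset is not None and any(e != 0 for e in self.plan.offset):
            return None
        for i in range(n):
            for j in range(n):
                if i != j and m[i, j] != 0:
                    return None
        return {s: -m[i, i] for i, s in enumerate(self.plan.analytic_states)}

    @cached_property
    def user_functions(self) -> dict:
        """Model-defined helper functions as callables over an environment."""
        funcs: dict = {}

        def make(fdef):
            def call(args, env, mask):
                from .evaluator import EvalEnv, exec_statements
                values = dict(env.values)
                sub = EvalEnv(values, env.n, env.rng, env.t, env.emit_spike,
                              env.deliver_spike, env.integrate_odes,
                              env.accessors, funcs)
                for (pname, _), a in zip(fdef.params, args):
                    values[pname] = a
                return exec_statements(fdef.statements, sub, mask)
            return call

        for f in self.ast.functions:
            funcs[f.name] = make(f)
        return funcs

    # -- serialization -------------------------------------------------------

    def artifact(self) -> dict:
        return {
            "name": self.name,
            "source": print_model(self.ast),
            "system": self.system.to_json(),
            "solver_plan": self.plan.to_json(),
            "parameters": dict(self.parameter_defaults),
            "moved_symbols": sorted(self.moved_symbols),
        }

    def artifact_json(self) -> str:
        return json.dumps(self.artifact(), indent=2)


def _evaluate_constants(model: A.Model) -> tuple[list[str], dict[str, float]]:
    """Evaluate parameter and internal initializers in declaration order."""
    names: list[str] = []
    values: dict[str, float] = {}
    env = EvalEnv(values, n=1)
    for block_kind in ("parameters", "internals"):
        block = model._decl_block(block_kind)
        if block is None:
            continue
        for d in block.declarations:
            names.append(d.name)
            if d.initializer is None:
                values[d.name] = 0.0
                continue
            v = eval_expr(d.initializer, env)
            if d.init_factor != 1.0:
                v = v * d.init_factor
            values[d.name] = float(v)
    return names, values


def compile_model(source: Union[str, A.Model], origin: str = "<memory>",
                  strict: bool = True) -> CompiledModel:
    """Validate, lower, and plan a model for execution.

    ``source`` is model text or an already-parsed AST.  With ``strict``
    (default), error diagnostics raise :class:`ModelError`.
    """
    model = parse_model(source, origin) if isinstance(source, str) else source
    checker = ModelChecker(model)
    diagnostics = checker.run()
    if strict and has_errors(diagnostics):
        first = next(d for d in diagnostics if d.severity == "error")
        first.origin = origin
        raise ModelError(first)
    scope = checker.scope

    system = lower_model(model, scope)
    param_names, param_defaults = _evaluate_constants(model)
    continuous = [p.name for p in model.continuous_ports()]
    spikes = [p.name for p in model.spike_ports()]
    plan = classify(system, set(param_names),
                    forbidden_inputs=set(continuous) | set(spikes))

    ode_states = list(system.state_names)
    plain = [d.name for d in (model.state.declarations if model.state else [])
             if d.name not in system.derivatives]
    state_names = ode_states + plain

    handlers = sorted(
        model.on_receive,
        key=lambda h: (-(h.priority if h.priority is not None else 0),
                       model.blocks.index(h)))

    return CompiledModel(
        ast=model, scope=scope, diagnostics=diagnostics, system=system,
        plan=plan, parameter_names=param_names,
        parameter_defaults=param_defaults, state_names=state_names,
        plain_states=plain, spike_port_names=spikes,
        continuous_port_names=continuous, handlers=handlers,
        conditions=list(model.on_condition),
        update_statements=list(model.update.statements) if model.update else [],
    )
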