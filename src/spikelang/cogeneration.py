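"""Neuron-synapse co-generation and the keyword-collision renamer.

In a network, every synapse converging on a neuron observes the same
postsynaptic spike train, so any synaptic state that depends only on
postsynaptic spiking (a postsynaptic trace and its time constant, say) is
duplicated across thousands of synapse instances.  The co-generation
transformer detects such state by a fixed-point dependency analysis, moves
it -- declarations, differential equations, and the statements that jump it
on postsynaptic spikes -- into the paired neuron model, and replaces the
synapse's references with accessor calls into the postsynaptic neuron
instance.  Parameters used exclusively by the moved dynamics travel along.

Which spike ports of the synapse count as postsynaptic is not expressed in
the language; it is supplied externally via pairing options (the
``post_ports`` entry of the code-generation options), keeping the synapse
model itself agnostic of how it will be wired.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import ast_nodes as A
from .compiler import CompiledModel, MovedTrace, compile_model
from .diagnostics import error, has_errors
from .printer import print_model
from .validation import check_model


@dataclass
class PairingOptions:
    neuron_model: str
    synapse_model: str
    post_ports: list[str] = field(default_factory=list)

    @staticmethod
    def from_codegen_options(options: dict) -> list["PairingOptions"]:
        """Parse ``{"neuron_synapse_pairs": [{"neuron": ..., "synapse": ...,
        "post_ports": [...]}]}``."""
        pairs = []
        for entry in options.get("neuron_synapse_pairs", []):
            pairs.append(PairingOptions(
                neuron_model=entry["neuron"],
                synapse_model=entry["synapse"],
                post_ports=list(entry.get("post_ports", []))))
        return pairs


@dataclass
class PairedModels:
    neuron_ast: A.Model
    synapse_ast: A.Model
    moved_symbols: set[str]
    renames: dict[str, str] = field(default_factory=dict)  # synapse name -> neuron name


# -- reference collection ---------------------------------------------------

def _names_in(expr: A.Expression) -> set[str]:
    out = set()
    for node in A.walk(expr):
        if isinstance(node, A.VarRef):
            out.add(node.name.rstrip("'"))
        elif isinstance(node, A.Convolve):
            out.add(node.kernel)
            out.add(node.port)
    return out


def _assigned_and_read(stmts: list[A.Statement]) -> tuple[set[str], dict[str, set[str]]]:
    """Names assigned in a statement list and, per assigned name, the names
    its assigning statements read (including compound-assignment reads)."""
    assigned: set[str] = set()
    reads: dict[str, set[str]] = {}
    for node in _walk_statements(stmts):
        if isinstance(node, A.Assignment):
            name = node.target.name
            assigned.add(name)
            r = _names_in(node.value)
            if node.op != "=":
                r.add(name)
            reads.setdefault(name, set()).update(r)
    return assigned, reads


def _walk_statements(stmts: list[A.Statement]):
    for s in stmts:
        yield s
        if isinstance(s, A.IfStmt):
            for _, body in s.branches:
                yield from _walk_statements(body)
        elif isinstance(s, (A.WhileStmt, A.ForStmt)):
            yield from _walk_statements(s.body)


def analyze_post_dependence(synapse: A.Model,
                            post_ports: Iterable[str]) -> set[str]:
    """State variables (plus their private parameters) movable to the neuron.

    A state is movable iff its differential equation and every statement
    assigning it reference only itself, other movable states, parameters,
    and designated postsynaptic ports -- and all its assignments sit inside
    onReceive handlers of those ports.  The closure is computed as a fixed
    point over the dependency graph.  Parameters used exclusively by movable
    dynamics are included in the returned set.
    """
    post_ports = set(post_ports)
    for p in post_ports:
        if p not in {q.name for q in synapse.spike_ports()}:
            raise error("unknown-port",
                        f"post port {p!r} is not a spike input port of "
                        f"{synapse.name!r}")
    state_names = {d.name for d in (synapse.state.declarations
                                    if synapse.state else [])}
    param_names = {d.name for d in (synapse.parameters.declarations
                                    if synapse.parameters else [])}
    param_names |= {d.name for d in (synapse.internals.declarations
                                     if synapse.internals else [])}

    derivs: dict[str, set[str]] = {}
    if synapse.equations:
        for item in synapse.equations.items:
            if isinstance(item, A.Equation):
                derivs[item.lhs_variable] = _names_in(item.rhs)

    # collect assignments per block kind
    post_assigned: dict[str, set[str]] = {}
    disqualified: set[str] = set()
    for h in synapse.on_receive:
        assigned, reads = _assigned_and_read(h.statements)
        if h.port in post_ports:
            for name, r in reads.items():
                post_assigned.setdefault(name, set()).update(r)
        else:
            disqualified |= assigned & state_names
    for block in ([synapse.update] if synapse.update else []) + \
            list(synapse.on_condition):
        assigned, _ = _assigned_and_read(block.statements)
        disqualified |= assigned & state_names

    candidates = set()
    for s in state_names:
        if s in disqualified:
            continue
        refs = derivs.get(s, set()) | post_assigned.get(s, set())
        # reading a non-post port or another non-state name blocks movability
        if any(r not in state_names and r not in param_names
               and r not in post_ports and r not in ("t", "e") for r in refs):
            continue
        candidates.add(s)

    changed = True
    while changed:
        changed = False
        for s in list(candidates):
            refs = derivs.get(s, set()) | post_assigned.get(s, set())
            if any(r in state_names and r != s and r not in candidates
                   for r in refs):
                candidates.discard(s)
                changed = True

    # parameters used exclusively by the movable dynamics
    movable_params = set()
    usage: dict[str, list[bool]] = {p: [] for p in param_names}

    def note_usage(names: set[str], inside_movable: bool):
        for nm in names:
            if nm in usage:
                usage[nm].append(inside_movable)

    if synapse.equations:
        for item in synapse.equations.items:
            if isinstance(item, A.Equation):
                note_usage(_names_in(item.rhs), item.lhs_variable in candidates)
            elif isinstance(item, (A.KernelDef, A.InlineDef)):
                note_usage(_names_in(item.expression), False)
    for h in synapse.on_receive:
        for node in _walk_statements(h.statements):
            if isinstance(node, A.Assignment):
                inside = (h.port in post_ports and node.target.name in candidates)
                note_usage(_names_in(node.value), inside)
            elif isinstance(node, (A.IfStmt, A.WhileStmt)):
                pass
    for block in ([synapse.update] if synapse.update else []) + \
            list(synapse.on_condition) + list(synapse.functions):
        for node in _walk_statements(block.statements):
            if isinstance(node, A.Assignment):
                note_usage(_names_in(node.value), False)
    for blk_kind in ("state", "parameters", "internals"):
        blk = synapse._decl_block(blk_kind)
        if blk:
            for d in blk.declarations:
                if d.initializer is not None:
                    note_usage(_names_in(d.initializer),
                               blk_kind == "state" and d.name in candidates)
    for p, uses in usage.items():
        if uses and all(uses):
            movable_params.add(p)

    return candidates | movable_params


# -- renaming ---------------------------------------------------------------

def rename_symbols(model: A.Model, mapping: dict[str, str]) -> None:
    """Consistently rename declared symbols and all their references, in place.

    Derivative references (``x'``) follow their base name.
    """
    if not mapping:
        return

    def rn(name: str) -> str:
        base = name.rstrip("'")
        primes = name[len(base):]
        return mapping.get(base, base) + primes

    for node in A.walk(model):
        if isinstance(node, A.VarRef):
            node.name = rn(node.name)
        elif isinstance(node, A.Declaration):
            node.name = rn(node.name)
            if isinstance(node.size, str):
                node.size = rn(node.size)
        elif isinstance(node, A.Equation):
            node.lhs_variable = rn(node.lhs_variable)
        elif isinstance(node, (A.KernelDef, A.InlineDef)):
            node.name = rn(node.name)
        elif isinstance(node, A.Convolve):
            node.kernel = rn(node.kernel)
            node.port = rn(node.port)
        elif isinstance(node, A.InputPort):
            node.name = rn(node.name)
        elif isinstance(node, A.OnReceive):
            node.port = rn(node.port)
        elif isinstance(node, A.FunctionDef):
            node.name = rn(node.name)
            node.params = [(rn(n), t) for n, t in node.params]
        elif isinstance(node, A.FunctionCall):
            node.name = rn(node.name)
        elif isinstance(node, A.ForStmt):
            node.var = rn(node.var)


def declared_names(model: A.Model) -> set[str]:
    names = set()
    for node in A.walk(model):
        if isinstance(node, A.Declaration):
            names.add(node.name)
        elif isinstance(node, A.InputPort):
            names.add(node.name)
        elif isinstance(node, (A.KernelDef, A.InlineDef)):
            names.add(node.name)
        elif isinstance(node, A.FunctionDef):
            names.add(node.name)
            names.update(n for n, _ in node.params)
    return names


def keyword_rename(model: A.Model, reserved: set[str]) -> A.Model:
    """Rename declared names colliding with target-language keywords.

    Appends ``__v`` (iterated until free) and rewrites all references;
    returns a transformed copy.
    """
    model = copy.deepcopy(model)
    declared = declared_names(model)
    mapping = {}
    for name in sorted(declared & set(reserved)):
        new = name + "__v"
        while new in declared or new in reserved or new in mapping.values():
            new += "__v"
        mapping[name] = new
    rename_symbols(model, mapping)
    return model


# -- the pairing transform --------------------------------------------------

def pair_transform(neuron: A.Model, synapse: A.Model,
                   options: PairingOptions) -> PairedModels:
    """Move postsynaptic-only state from the synapse into the neuron.

    The neuron gains the moved declarations, equations, and per-own-spike
    jump statements (inserted into every onCondition block that emits a
    spike); the synapse's remaining references to moved states become
    accessor calls ``__post__<name>()`` resolved against the postsynaptic
    neuron instance at the event's query time.  Both transformed models
    re-validate and print as ordinary model text.
    """
    movable = analyze_post_dependence(synapse, options.post_ports)
    neuron = copy.deepcopy(neuron)
    synapse = copy.deepcopy(synapse)
    if not movable:
        return PairedModels(neuron, synapse, set())

    syn_states = {d.name for d in (synapse.state.declarations
                                   if synapse.state else [])}
    moved_states = movable & syn_states
    moved_params = movable - moved_states

    # collision-free names on the neuron side
    neuron_names = declared_names(neuron) | {"t", "e"}
    renames: dict[str, str] = {}
    for name in sorted(movable):
        new = name
        while new in neuron_names:
            new = f"{name}__for_{synapse.name}"
            if new in neuron_names:
                new += "__v"
                while new in neuron_names:
                    new += "__v"
            break
        renames[name] = new
        neuron_names.add(new)

    # -- harvest the moved material from the synapse -------------------------
    def pop_declarations(block_kind: str, names: set[str]) -> list[A.Declaration]:
        blk = synapse._decl_block(block_kind)
        taken = []
        if blk:
            keep = []
            for d in blk.declarations:
                (taken if d.name in names else keep).append(d)
            blk.declarations = keep
        return taken

    moved_decls = pop_declarations("state", moved_states)
    moved_param_decls = (pop_declarations("parameters", moved_params)
                         + pop_declarations("internals", moved_params))

    moved_eqs: list[A.Equation] = []
    if synapse.equations:
        keep_items = []
        for item in synapse.equations.items:
            if isinstance(item, A.Equation) and item.lhs_variable in moved_states:
                moved_eqs.append(item)
            else:
                keep_items.append(item)
        synapse.equations.items = keep_items

    moved_jumps: list[A.Statement] = []
    for h in synapse.on_receive:
        if h.port not in options.post_ports:
            continue
        keep = []
        for s in h.statements:
            if isinstance(s, A.Assignment) and s.target.name in moved_states:
                moved_jumps.append(s)
            else:
                keep.append(s)
        h.statements = keep
    # drop post handlers left with an empty body
    synapse.blocks = [b for b in synapse.blocks
                      if not (isinstance(b, A.OnReceive)
                              and b.port in options.post_ports
                              and not b.statements)]

    # -- rewrite remaining synapse references as accessors -------------------
    class _Rewriter:
        def rewrite_expr(self, expr: A.Expression) -> A.Expression:
            if isinstance(expr, A.VarRef) and expr.name.rstrip("'") in moved_states:
                return A.FunctionCall(
                    name=f"__post__{renames[expr.name.rstrip(chr(39))]}",
                    args=[], span=expr.span)
            for fname in ("operand", "left", "right", "value", "index"):
                child = getattr(expr, fname, None)
                if isinstance(child, A.Expression):
                    setattr(expr, fname, self.rewrite_expr(child))
            if isinstance(expr, A.FunctionCall):
                expr.args = [self.rewrite_expr(a) for a in expr.args]
            return expr

        def rewrite_stmts(self, stmts: list[A.Statement]) -> None:
            for s in stmts:
                if isinstance(s, A.Assignment):
                    s.value = self.rewrite_expr(s.value)
                elif isinstance(s, A.ExprStmt):
                    s.call = self.rewrite_expr(s.call)
                elif isinstance(s, A.ReturnStmt) and s.value is not None:
                    s.value = self.rewrite_expr(s.value)
                elif isinstance(s, A.DeclarationStmt):
                    if s.declaration.initializer is not None:
                        s.declaration.initializer = self.rewrite_expr(
                            s.declaration.initializer)
                elif isinstance(s, A.IfStmt):
                    s.branches = [(self.rewrite_expr(c) if c is not None else None,
                                   b) for c, b in s.branches]
                    for _, b in s.branches:
                        self.rewrite_stmts(b)
                elif isinstance(s, (A.WhileStmt,)):
                    s.condition = self.rewrite_expr(s.condition)
                    self.rewrite_stmts(s.body)
                elif isinstance(s, A.ForStmt):
                    self.rewrite_stmts(s.body)

    rewriter = _Rewriter()
    for h in synapse.on_receive:
        rewriter.rewrite_stmts(h.statements)
    if synapse.update:
        rewriter.rewrite_stmts(synapse.update.statements)
    for c in synapse.on_condition:
        c.condition = rewriter.rewrite_expr(c.condition)
        rewriter.rewrite_stmts(c.statements)
    if synapse.equations:
        for item in synapse.equations.items:
            if isinstance(item, A.Equation):
                item.rhs = rewriter.rewrite_expr(item.rhs)
            else:
                item.expression = rewriter.rewrite_expr(item.expression)

    # -- graft the moved material onto the neuron ----------------------------
    def as_model(decls, eqs, jumps) -> None:
        pseudo = A.Model(name="__moved__", blocks=[
            A.DeclarationsBlock(kind="state", declarations=decls),
            A.DeclarationsBlock(kind="parameters", declarations=moved_param_decls),
            A.EquationsBlock(items=eqs),
            A.UpdateBlock(statements=jumps),
        ])
        rename_symbols(pseudo, renames)

    as_model(moved_decls, moved_eqs, moved_jumps)

    if neuron.state is None:
        neuron.blocks.insert(0, A.DeclarationsBlock(kind="state", declarations=[]))
    neuron.state.declarations.extend(moved_decls)
    if moved_param_decls:
        if neuron.parameters is None:
            neuron.blocks.insert(1, A.DeclarationsBlock(kind="parameters",
                                                        declarations=[]))
        neuron.parameters.declarations.extend(moved_param_decls)
    if moved_eqs:
        if neuron.equations is None:
            neuron.blocks.append(A.EquationsBlock(items=[]))
        neuron.equations.items.extend(moved_eqs)

    # the moved jump fires on the neuron's own spike: append to every
    # onCondition block that emits one
    def emits(stmts) -> bool:
        return any(isinstance(n, A.FunctionCall) and n.name == "emit_spike"
                   for s in _walk_statements(stmts) for n in A.walk(s))

    spike_conditions = [c for c in neuron.on_condition if emits(c.statements)]
    if moved_jumps and not spike_conditions:
        raise error("no-spike-condition",
                    f"neuron {neuron.name!r} has no spike-emitting onCondition "
                    "to host the moved postsynaptic jumps")
    for c in spike_conditions:
        c.statements.extend(copy.deepcopy(moved_jumps))

    moved_names = {renames[m] for m in movable}
    return PairedModels(neuron, synapse, moved_names, renames)


# -- compilation of a pair --------------------------------------------------

def _jump_amount(stmt: A.Statement) -> float:
    if (isinstance(stmt, A.Assignment) and stmt.op == "+="
            and isinstance(stmt.value, A.NumberLiteral)):
        return float(stmt.value.value)
    return 1.0


def pair_compile(neuron: A.Model, synapse: A.Model,
                 options: PairingOptions) -> tuple[CompiledModel, CompiledModel]:
    """Run the co-generation transform and compile both resulting models."""
    paired = pair_transform(neuron, synapse, options)
    n_diags = check_model(paired.neuron_ast)
    s_diags = check_model(paired.synapse_ast)
    if has_errors(n_diags) or has_errors(s_diags):
        bad = next(d for d in (n_diags + s_diags) if d.severity == "error")
        raise error(bad.code, f"co-generated pair fails validation: {bad.message}",
                    bad.location)
    cn = compile_model(paired.neuron_ast)
    cs = compile_model(paired.synapse_ast)
    syn_states = {d.name for d in (synapse.state.declarations
                                   if synapse.state else [])}
    for old, new in paired.renames.items():
        if old not in syn_states:
            continue  # moved parameter, no trace needed
        rate_expr = cn.system.derivatives.get(new)
        tau_param = ""
        if rate_expr is not None:
            # informational only; the accessor reads the grid history
            syms = [str(s) for s in rate_expr.free_symbols if str(s) != new]
            tau_param = syms[0] if len(syms) == 1 else ""
        cn.moved_traces.append(MovedTrace(
            state=new, tau_param=tau_param, jump=1.0,
            accessor=f"__post__{new}"))
    cn.moved_symbols = set(paired.moved_symbols)
    cs.moved_symbols = set(paired.moved_symbols)
    return cn, cs


def load_codegen_options(path_or_dict) -> list[PairingOptions]:
    if isinstance(path_or_dict, dict):
        return PairingOptions.from_codegen_options(path_or_dict)
    with open(path_or_dict) as fh:
        return PairingOptions.from_codegen_options(json.load(fh))
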