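"""Node-level circuit assembly and compilation to a flat reaction system.

The central abstraction is the *node*: a regulatory unit (promoter + gene +
terminator) whose species (mRNA, protein, sgRNA, promoter DNA ...) and
reactions are described once by a :class:`NodeModelSpec` template.  A
:class:`Circuit` is a declarative collection of named nodes, regulation edges
between them, shared proteases, inducers and time-varying rules.
:func:`Circuit.compile` instantiates the template for every node, wires the
regulation inputs, and emits a :class:`CompiledModel` — an ordered species
list, a parameter table, mass-balance reactions with evaluable propensities,
and the resulting ODE right-hand side.

Regulation edges are written in a small text grammar::

    "N1 |- N3"           # node N1 repressed by N3   (default HILL channel)
    "N2 <- Y"            # node N2 activated by Y (external species -> parameter)
    "N1:CRISPRI |- N3"   # repression through the CRISPRI input channel

Multiple regulators on one promoter combine multiplicatively on HILL-type
channels (independent-site assumption); CRISPRI regulators instead compete
for explicit free/bound promoter-DNA states via injected binding reactions.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .rules import Rule

__all__ = [
    "NodeModelSpec",
    "ReactionTemplate",
    "InputChannel",
    "RegulationEdge",
    "Reaction",
    "Circuit",
    "CompiledModel",
    "parse_edge",
    "register_model",
    "get_model",
    "registered_models",
]

_IDENT = re.compile(r"\b[A-Za-z_]\w*\b")

# Factor templates for HILL-type channels.  {R} is the regulator symbol, K and
# n resolve through the target node's parameter scope.
_REPRESSION = "(1.0/(1.0+({R}/{K})**{n}))"
_ACTIVATION = "((({R}/{K})**{n})/(1.0+(({R}/{K})**{n})))"


@dataclass(frozen=True)
class ReactionTemplate:
    """One reaction of a node model, over local (role-level) symbols.

    ``stoich`` maps species roles to net stoichiometric coefficients;
    ``rate`` is an arithmetic expression over roles and parameter symbols.
    If ``modulated_by`` names input channels, the literal token ``REG`` in
    ``rate`` is replaced at compile time by the product of the regulation
    factors arriving on those channels (``1.0`` when unregulated).
    """

    name: str
    stoich: dict
    rate: str
    modulated_by: tuple = ()


@dataclass(frozen=True)
class InputChannel:
    """How an incoming edge on this channel acts on the target node.

    ``kind`` is ``"factor"`` (edge contributes a multiplicative regulation
    factor to the reactions that declare the channel in ``modulated_by``) or
    ``"reactions"`` (edge injects new species/reactions via the model's
    ``injector`` callback, e.g. CRISPRi DNA-binding).
    """

    kind: str
    repression: str = _REPRESSION
    activation: str = _ACTIVATION
    K: str = "K"
    n: str = "n"


@dataclass
class NodeModelSpec:
    """Template of species, reactions and input channels for one node kind."""

    model_id: str
    species_roles: list
    initial: dict
    reactions: list
    input_channels: dict
    parameter_defaults: dict
    parameter_scope: dict = field(default_factory=dict)  # default "common"
    output_role: str | None = None  # species seen by downstream HILL edges
    protease_substrate_role: str | None = None
    # injector(compiler, node, edges) -> None; used by "reactions" channels
    injector: Callable | None = None
    regulator_role: str | None = None  # species used when this node regulates
    # via a "reactions" channel (e.g. its sgRNA)

    def __post_init__(self):
        roles = set(self.species_roles)
        for rt in self.reactions:
            for role in rt.stoich:
                if role not in roles:
                    raise ValueError(
                        f"model {self.model_id!r}: reaction {rt.name!r} references "
                        f"undeclared species role {role!r}"
                    )
        for ch, spec in self.input_channels.items():
            if spec.kind not in ("factor", "reactions"):
                raise ValueError(f"channel {ch!r}: kind must be 'factor' or 'reactions'")

    def scope(self, symbol: str) -> str:
        return self.parameter_scope.get(symbol, "common")


# ---------------------------------------------------------------------------
# model registry

_MODEL_REGISTRY: dict = {}


def register_model(spec: NodeModelSpec) -> None:
    _MODEL_REGISTRY[spec.model_id] = spec


def get_model(model_id: str) -> NodeModelSpec:
    try:
        return _MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown node model {model_id!r}; registered: {sorted(_MODEL_REGISTRY)}"
        ) from None


def registered_models() -> list:
    return sorted(_MODEL_REGISTRY)


# ---------------------------------------------------------------------------
# circuit-level records


@dataclass(frozen=True)
class RegulationEdge:
    target: str
    regulator: str
    sign: str  # "repression" | "activation"
    channel: str = "HILL"

    def key(self):
        return (self.target, self.regulator, self.channel)

    def label(self) -> str:
        op = "|-" if self.sign == "repression" else "<-"
        ch = "" if self.channel == "HILL" else f":{self.channel}"
        return f"{self.target}{ch} {op} {self.regulator}"


_EDGE_RE = re.compile(
    r"^\s*(?P<target>[A-Za-z_]\w*)\s*(?::\s*(?P<channel>[A-Za-z_]\w*))?\s*"
    r"(?P<op>\|-|<-)\s*(?P<reg>[A-Za-z_]\w*)\s*$"
)

# the paper-facing alias for the CRISPRi input channel
_CHANNEL_ALIASES = {"NOHILL": "CRISPRI"}


def parse_edge(expr: str) -> RegulationEdge:
    """Parse ``"TARGET[:CHANNEL] |- REGULATOR"`` / ``"... <- ..."`` text."""
    m = _EDGE_RE.match(expr)
    if not m:
        raise ValueError(
            f"cannot parse edge {expr!r}; expected 'TARGET[:CHANNEL] |- REG' or '<-'"
        )
    channel = m.group("channel") or "HILL"
    channel = _CHANNEL_ALIASES.get(channel, channel)
    sign = "repression" if m.group("op") == "|-" else "activation"
    return RegulationEdge(m.group("target"), m.group("reg"), sign, channel)


@dataclass
class Protease:
    name: str
    targets: list
    kcat: float
    Km: float
    conc: float


@dataclass
class Inducer:
    """Saturating scaling ``I/(K_I + I)`` of one activation edge's factor."""

    name: str
    edge: RegulationEdge
    K: float
    conc: float = 0.0


# ---------------------------------------------------------------------------
# compiled model


@dataclass
class Reaction:
    name: str
    stoich: dict  # global species name -> coefficient
    rate_law: str  # human-readable expression over global symbols


class CompiledModel:
    """Flat species/parameter/reaction system with an evaluable RHS.

    ``propensities(y, p, t)`` evaluates every reaction rate at state ``y``
    (concentrations, nM) and parameter vector ``p``; ``rhs(t, y)`` is the
    stoichiometry-weighted sum, suitable for ``scipy.integrate.solve_ivp``.
    Expressions are compiled once into a single python function, and remain
    valid for array-valued states (used by the spatial solvers, where each
    species is a 2-D field).
    """

    def __init__(
        self,
        species: list,
        init: np.ndarray,
        param_names: list,
        param_values: np.ndarray,
        reactions: list,
        conserved: list,
        rules: list,
    ):
        self.species = list(species)
        self.init = np.asarray(init, dtype=float)
        self.param_names = list(param_names)
        self.param_values = np.asarray(param_values, dtype=float)
        self.reactions = list(reactions)
        self.conserved = list(conserved)  # (label, {species: coeff})
        self.rules = list(rules)
        self._sidx = {s: i for i, s in enumerate(self.species)}
        self._pidx = {s: i for i, s in enumerate(self.param_names)}
        self._build()

    # -- construction -------------------------------------------------------

    def _build(self):
        ns, nr = len(self.species), len(self.reactions)
        S = np.zeros((ns, nr))
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoich.items():
                S[self._sidx[sp], j] += coeff
        self.stoich_matrix = S

        def sub(mo):
            name = mo.group(0)
            if name in self._sidx:
                return f"y[{self._sidx[name]}]"
            if name in self._pidx:
                return f"p[{self._pidx[name]}]"
            if name == "t":
                return "t"
            raise KeyError(f"unresolvable symbol {name!r} in rate law")

        exprs = [_IDENT.sub(sub, rxn.rate_law) for rxn in self.reactions]
        body = ", ".join(exprs) if exprs else ""
        src = f"def _props(y, p, t):\n    return [{body}]\n"
        env: dict = {}
        exec(compile(src, "<grnsim-propensities>", "exec"), env)
        self._props = env["_props"]
        self._forcing = [
            (self._pidx[r.symbol], r.waveform) for r in self.rules
        ]

    # -- parameter access ----------------------------------------------------

    def has_symbol(self, name: str) -> bool:
        return name in self._pidx or name in self._sidx

    def get_param(self, name: str) -> float:
        return float(self.param_values[self._pidx[name]])

    def with_params(self, **overrides) -> "CompiledModel":
        """Copy of the model with some parameter values replaced."""
        m = copy.copy(self)
        m.param_values = self.param_values.copy()
        for k, v in overrides.items():
            if k not in self._pidx:
                raise KeyError(f"unknown parameter {k!r}")
            m.param_values[m._pidx[k]] = float(v)
        return m

    def with_rules(self, rules: Iterable[Rule]) -> "CompiledModel":
        rules = list(rules)
        seen = set()
        for r in rules:
            if r.symbol in seen:
                raise ValueError(f"overlapping rules on symbol {r.symbol!r}")
            seen.add(r.symbol)
            if r.symbol not in self._pidx:
                raise KeyError(f"rule on unknown parameter {r.symbol!r}")
        m = copy.copy(self)
        m.rules = rules
        m._forcing = [(m._pidx[r.symbol], r.waveform) for r in rules]
        return m

    def params_at(self, t: float) -> np.ndarray:
        p = self.param_values
        if self._forcing:
            p = p.copy()
            for idx, wf in self._forcing:
                p[idx] = wf(t)
        return p

    # -- evaluation ----------------------------------------------------------

    def propensities(self, y, p=None, t: float = 0.0) -> np.ndarray:
        if p is None:
            p = self.params_at(t)
        return np.array(self._props(y, p, t), dtype=float)

    def rhs(self, t, y):
        p = self.params_at(t)
        props = self._props(y, p, t)
        if np.ndim(y) == 1:
            return self.stoich_matrix @ np.asarray(props, dtype=float)
        # array-valued species fields (spatial use): contract manually
        out = np.zeros_like(y, dtype=float)
        for j, a in enumerate(props):
            col = self.stoich_matrix[:, j]
            for i in np.nonzero(col)[0]:
                out[i] += col[i] * a
        return out

    def conserved_totals(self, y) -> np.ndarray:
        return np.array(
            [sum(c * y[self._sidx[s]] for s, c in coeffs.items()) for _, coeffs in self.conserved]
        )

    def index(self, species: str) -> int:
        return self._sidx[species]

    def __repr__(self):
        return (
            f"<CompiledModel {len(self.species)} species, "
            f"{len(self.reactions)} reactions, {len(self.param_names)} parameters>"
        )


# ---------------------------------------------------------------------------
# the circuit builder


class Circuit:
    """Declarative circuit: nodes, edges, proteases, inducers, rules."""

    def __init__(self, default_model: str | None = None):
        self.default_model = default_model
        self.nodes: dict = {}  # name -> model_id
        self.edges: list = []
        self.proteases: list = []
        self.inducers: list = []
        self.rules: list = []
        self.parameters: dict = {}  # common overrides / external symbols
        self.node_parameters: dict = {}  # (node, symbol) -> value
        self.initial_conditions: dict = {}  # (node, role) or species -> value
        self.two_input_params: dict = {}  # target node -> param dict

    # -- assembly ------------------------------------------------------------

    def add_node(self, name: str, model_id: str | None = None) -> "Circuit":
        if name in self.nodes:
            raise ValueError(f"duplicate node name {name!r}")
        model_id = model_id or self.default_model
        if model_id is None:
            raise ValueError("no node model given and no circuit default set")
        get_model(model_id)  # validates registration
        self.nodes[name] = model_id
        return self

    def add_regulation(self, edge) -> "Circuit":
        if isinstance(edge, str):
            edge = parse_edge(edge)
        if edge.target not in self.nodes:
            raise ValueError(f"unknown target node {edge.target!r}")
        spec = get_model(self.nodes[edge.target])
        if edge.channel not in spec.input_channels:
            raise ValueError(
                f"node {edge.target!r} (model {spec.model_id!r}) has no input "
                f"channel {edge.channel!r}"
            )
        if (
            spec.input_channels[edge.channel].kind == "reactions"
            and edge.regulator not in self.nodes
        ):
            raise ValueError(
                f"channel {edge.channel!r} requires a node regulator, "
                f"got {edge.regulator!r}"
            )
        self.edges.append(edge)
        return self

    def add_protease(
        self, name: str, targets: Sequence[str], kcat: float, Km: float, conc: float = 1.0
    ) -> "Circuit":
        if Km <= 0:
            raise ValueError("protease half-saturation Km must be positive")
        for tgt in targets:
            if tgt not in self.nodes:
                raise ValueError(f"protease {name!r}: unknown target node {tgt!r}")
            if get_model(self.nodes[tgt]).protease_substrate_role is None:
                raise ValueError(
                    f"protease {name!r}: node {tgt!r} has no protease substrate"
                )
        self.proteases.append(Protease(name, list(targets), kcat, Km, conc))
        return self

    def add_inducer(
        self, name: str, edge, K: float, conc: float = 0.0
    ) -> "Circuit":
        if isinstance(edge, str):
            edge = parse_edge(edge)
        keys = [e.key() for e in self.edges]
        if edge.key() not in keys:
            raise ValueError(f"inducer {name!r}: no such edge {edge.label()!r}")
        if edge.sign != "activation":
            raise ValueError(f"inducer {name!r}: target edge must be an activation")
        self.inducers.append(Inducer(name, edge, K, conc))
        return self

    def add_two_input(self, target: str, params: dict) -> "Circuit":
        """Attach a two-input (chemical x light) drive to ``target``'s promoter.

        ``params`` supplies K_ara, n_ara, K_light, n_light, k_light; the input
        symbols ``ara`` and ``I_light`` become settable model parameters.
        """
        edge = RegulationEdge(target, "ara_light", "activation", "TWOINPUT")
        self.add_regulation(edge)
        self.two_input_params[target] = dict(params)
        return self

    def set_rule(self, rule: Rule) -> "Circuit":
        self.rules.append(rule)
        return self

    def set_param(self, symbol: str, value: float, node: str | None = None) -> "Circuit":
        if node is None:
            self.parameters[symbol] = float(value)
        else:
            if node not in self.nodes:
                raise ValueError(f"unknown node {node!r}")
            self.node_parameters[(node, symbol)] = float(value)
        return self

    def set_initial(self, node: str, role: str, value: float) -> "Circuit":
        self.initial_conditions[(node, role)] = float(value)
        return self

    def remove_node(self, name: str) -> "Circuit":
        if name not in self.nodes:
            raise ValueError(f"unknown node {name!r}")
        del self.nodes[name]
        self.edges = [
            e for e in self.edges if e.target != name and e.regulator != name
        ]
        for pr in self.proteases:
            pr.targets = [t for t in pr.targets if t != name]
        self.node_parameters = {
            k: v for k, v in self.node_parameters.items() if k[0] != name
        }
        self.initial_conditions = {
            k: v
            for k, v in self.initial_conditions.items()
            if not (isinstance(k, tuple) and k[0] == name)
        }
        self.two_input_params.pop(name, None)
        return self

    # -- views ---------------------------------------------------------------

    def topology_graph(self) -> nx.DiGraph:
        """Directed graph with one vertex per node and one per interaction."""
        g = nx.DiGraph()
        for name, model_id in self.nodes.items():
            g.add_node(name, kind="node", model=model_id)
        for e in self.edges:
            iv = e.label()
            g.add_node(iv, kind="interaction", sign=e.sign, channel=e.channel)
            g.add_edge(e.regulator, iv)
            g.add_edge(iv, e.target)
        return g

    # -- compilation ---------------------------------------------------------

    def compile(self) -> CompiledModel:
        return _Compiler(self).run()


class _Compiler:
    """Instantiates node-model templates into a flat reaction system."""

    def __init__(self, circuit: Circuit):
        self.c = circuit
        self.species: list = []
        self.init: list = []
        self.params: dict = {}  # name -> value (insertion-ordered)
        self.reactions: list = []
        self.conserved: list = []

    # shared helpers used by model injectors ---------------------------------

    def add_species(self, name: str, value: float) -> None:
        if name not in self.species:
            self.species.append(name)
            self.init.append(float(value))

    def add_param(self, name: str, value: float) -> None:
        self.params.setdefault(name, float(value))

    def add_reaction(self, name: str, stoich: dict, rate: str) -> None:
        self.reactions.append(Reaction(name, dict(stoich), rate))

    def add_conserved(self, label: str, coeffs: dict) -> None:
        self.conserved.append((label, dict(coeffs)))

    def qualify(self, node: str, symbol: str) -> str:
        """Global parameter name for ``symbol`` in ``node``'s scope."""
        spec = get_model(self.c.nodes[node])
        if spec.scope(symbol) == "individual" or (node, symbol) in self.c.node_parameters:
            return f"{symbol}_{node}"
        return symbol

    def species_name(self, node: str, role: str) -> str:
        return f"{role}_{node}"

    # main pass --------------------------------------------------------------

    def run(self) -> CompiledModel:
        c = self.c
        edges_by_target: dict = {}
        for e in c.edges:
            edges_by_target.setdefault(e.target, []).append(e)

        # species and parameters, node by node (deterministic ordering)
        for node, model_id in c.nodes.items():
            spec = get_model(model_id)
            for role in spec.species_roles:
                v = c.initial_conditions.get((node, role), spec.initial.get(role, 0.0))
                self.add_species(self.species_name(node, role), v)
            for sym, default in spec.parameter_defaults.items():
                name = self.qualify(node, sym)
                value = c.node_parameters.get((node, sym), c.parameters.get(sym, default))
                self.add_param(name, value)

        # external regulators (non-node symbols on factor channels) -> params
        for e in c.edges:
            if e.regulator not in c.nodes and e.channel != "TWOINPUT":
                self.add_param(e.regulator, c.parameters.get(e.regulator, 0.0))

        # inducer concentrations and half-saturations
        for ind in c.inducers:
            self.add_param(ind.name, c.parameters.get(ind.name, ind.conc))
            self.add_param(f"K_{ind.name}", ind.K)

        # two-input drive parameters
        for target, pars in c.two_input_params.items():
            self.add_param("ara", c.parameters.get("ara", 0.0))
            self.add_param("I_light", c.parameters.get("I_light", 0.0))
            for sym in ("K_ara", "n_ara", "K_light", "n_light", "k_light"):
                self.add_param(f"{sym}_{target}", pars[sym])

        # per-node base reactions with regulation factors spliced in
        for node, model_id in c.nodes.items():
            spec = get_model(model_id)
            factors = self._factors(node, spec, edges_by_target.get(node, []))
            for rt in spec.reactions:
                rate = self._instantiate_rate(node, spec, rt, factors)
                stoich = {
                    self.species_name(node, role): coeff for role, coeff in rt.stoich.items()
                }
                self.add_reaction(f"{rt.name}_{node}", stoich, rate)

        # channel-injected reactions (e.g. CRISPRi binding)
        for node, model_id in c.nodes.items():
            spec = get_model(model_id)
            injected = [
                e
                for e in edges_by_target.get(node, [])
                if spec.input_channels[e.channel].kind == "reactions"
            ]
            if injected:
                if spec.injector is None:
                    raise ValueError(
                        f"model {model_id!r} declares a reaction channel but no injector"
                    )
                spec.injector(self, node, injected)

        # shared-protease Michaelis-Menten queue
        for pr in self.c.proteases:
            self._protease_reactions(pr)

        # validate rule symbols
        for r in c.rules:
            if r.symbol not in self.params:
                raise ValueError(f"rule on unknown symbol {r.symbol!r}")

        return CompiledModel(
            species=self.species,
            init=np.array(self.init, dtype=float),
            param_names=list(self.params),
            param_values=np.array(list(self.params.values()), dtype=float),
            reactions=self.reactions,
            conserved=self.conserved,
            rules=list(c.rules),
        )

    # factor-channel handling -----------------------------------------------

    def _regulator_symbol(self, edge: RegulationEdge) -> str:
        reg = edge.regulator
        if reg in self.c.nodes:
            rspec = get_model(self.c.nodes[reg])
            role = rspec.output_role
            if role is None:
                raise ValueError(
                    f"node {reg!r} (model {rspec.model_id!r}) has no output species "
                    "and cannot regulate through a factor channel"
                )
            return self.species_name(reg, role)
        return reg  # external species, held as a parameter

    def _factors(self, node: str, spec: NodeModelSpec, edges: list) -> dict:
        """Per-channel multiplicative factor expressions for ``node``."""
        by_channel: dict = {}
        inducers_by_edge = {ind.edge.key(): ind for ind in self.c.inducers}
        for e in edges:
            ch = spec.input_channels[e.channel]
            if ch.kind != "factor":
                continue
            if e.channel == "TWOINPUT":
                f = self._two_input_factor(node)
            else:
                template = ch.repression if e.sign == "repression" else ch.activation
                f = template.format(
                    R=self._regulator_symbol(e),
                    K=self.qualify(node, ch.K),
                    n=self.qualify(node, ch.n),
                )
            ind = inducers_by_edge.get(e.key())
            if ind is not None:
                f = f"({f}*({ind.name}/(K_{ind.name}+{ind.name})))"
            by_channel.setdefault(e.channel, []).append(f)
        return {ch: "*".join(fs) for ch, fs in by_channel.items()}

    def _two_input_factor(self, node: str) -> str:
        x = f"((ara/K_ara_{node})**n_ara_{node})"
        y = f"((I_light/K_light_{node})**n_light_{node})"
        return f"(({x}+k_light_{node}*{y})/((1.0+{x})*(1.0+{y})))"

    def _instantiate_rate(
        self, node: str, spec: NodeModelSpec, rt: ReactionTemplate, factors: dict
    ) -> str:
        reg = "*".join(factors[ch] for ch in rt.modulated_by if ch in factors) or "1.0"

        def sub(mo):
            name = mo.group(0)
            if name == "REG":
                return reg
            if name in spec.species_roles:
                return self.species_name(node, name)
            if name in spec.parameter_defaults:
                return self.qualify(node, name)
            if name == "t":
                return "t"
            raise KeyError(
                f"model {spec.model_id!r}, reaction {rt.name!r}: "
                f"unresolvable symbol {name!r}"
            )

        return _IDENT.sub(sub, rt.rate)

    # proteases ---------------------------------------------------------------

    def _protease_reactions(self, pr: Protease) -> None:
        if not pr.targets:
            return
        self.add_param(f"kcat_{pr.name}", pr.kcat)
        self.add_param(f"Km_{pr.name}", pr.Km)
        self.add_param(f"E_{pr.name}", pr.conc)
        substrates = []
        for tgt in pr.targets:
            role = get_model(self.c.nodes[tgt]).protease_substrate_role
            substrates.append(self.species_name(tgt, role))
        pool = "+".join(substrates)
        for sub in substrates:
            rate = f"kcat_{pr.name}*E_{pr.name}*{sub}/(Km_{pr.name}+({pool}))"
            self.add_reaction(f"proteolysis_{pr.name}_{sub}", {sub: -1}, rate)
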