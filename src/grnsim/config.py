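"""Declarative circuit configuration (YAML/JSON).

Schema (version 1)::

    schema: 1
    model: elowitz              # default node model
    nodes: [N1, N2, N3]         # or {N1: elowitz, N4: tomazou}
    edges: ["N2 |- N1", "N3 |- N2", "N1 |- N3"]
    proteases:
      - {name: C, targets: [N1, N2, N3], kcat: 1.2, Km: 40.0, conc: 50.0}
    inducers:
      - {name: I2, edge: "N2 <- Y", K: 10.0, conc: 10.0}
    two_input:
      - {target: N1, params: {K_ara: 1e-3, n_ara: 1, K_light: 30,
                              n_light: 2, k_light: 0.125}}
    rules:
      - {symbol: LIGHT, waveform: square, period: 1440, duty: 0.4166,
         low: 0, high: 15}
    parameters: {a1: 0.5, "K@N2": 80.0}      # "@node" scopes a parameter
    initial_conditions: {"P@N1": 100.0}

Unknown top-level keys are errors, not warnings.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .circuit import Circuit
from .rules import Constant, Rule, Sine, Square, Table
from . import models  # noqa: F401

__all__ = ["load_circuit", "circuit_to_config", "save_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema",
    "model",
    "nodes",
    "edges",
    "proteases",
    "inducers",
    "two_input",
    "rules",
    "parameters",
    "initial_conditions",
    "spatial",
}


def _load_mapping(source) -> dict:
    if isinstance(source, dict):
        return source
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _waveform(entry: dict):
    kind = entry.get("waveform", "constant")
    if kind == "constant":
        return Constant(float(entry["value"]))
    if kind == "square":
        return Square(
            period=float(entry["period"]),
            duty=float(entry["duty"]),
            low=float(entry.get("low", 0.0)),
            high=float(entry["high"]),
            phase=float(entry.get("phase", 0.0)),
        )
    if kind == "sine":
        return Sine(
            period=float(entry["period"]),
            mean=float(entry["mean"]),
            amplitude=float(entry["amplitude"]),
            phase=float(entry.get("phase", 0.0)),
        )
    if kind == "table":
        return Table(tuple(entry["times"]), tuple(entry["values"]))
    raise ValueError(f"unknown waveform kind {kind!r}")


def _split_scoped(key: str):
    if "@" in key:
        sym, node = key.split("@", 1)
        return sym.strip(), node.strip()
    return key.strip(), None


def load_circuit(source) -> Circuit:
    """Build a :class:`Circuit` from a config mapping or YAML/JSON path."""
    cfg = _load_mapping(source)
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if int(cfg.get("schema", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {cfg.get('schema')}")

    c = Circuit(default_model=cfg.get("model"))
    nodes = cfg.get("nodes", [])
    if isinstance(nodes, dict):
        for name, model_id in nodes.items():
            c.add_node(name, model_id)
    else:
        for name in nodes:
            c.add_node(name)
    for expr in cfg.get("edges", []):
        c.add_regulation(expr)
    for pr in cfg.get("proteases", []):
        c.add_protease(
            pr["name"],
            pr["targets"],
            kcat=float(pr["kcat"]),
            Km=float(pr["Km"]),
            conc=float(pr.get("conc", 1.0)),
        )
    for ind in cfg.get("inducers", []):
        c.add_inducer(
            ind["name"], ind["edge"], K=float(ind["K"]), conc=float(ind.get("conc", 0.0))
        )
    for ti in cfg.get("two_input", []):
        c.add_two_input(ti["target"], {k: float(v) for k, v in ti["params"].items()})
    for key, value in (cfg.get("parameters") or {}).items():
        sym, node = _split_scoped(str(key))
        c.set_param(sym, float(value), node=node)
    for key, value in (cfg.get("initial_conditions") or {}).items():
        role, node = _split_scoped(str(key))
        if node is None:
            raise ValueError(
                f"initial condition {key!r} must be scoped as 'role@node'"
            )
        c.set_initial(node, role, float(value))
    for entry in cfg.get("rules", []):
        c.set_rule(Rule(entry["symbol"], _waveform(entry)))
    return c


def _waveform_to_dict(symbol: str, wf) -> dict:
    if isinstance(wf, Constant):
        return {"symbol": symbol, "waveform": "constant", "value": wf.value}
    if isinstance(wf, Square):
        return {
            "symbol": symbol,
            "waveform": "square",
            "period": wf.period,
            "duty": wf.duty,
            "low": wf.low,
            "high": wf.high,
            "phase": wf.phase,
        }
    if isinstance(wf, Sine):
        return {
            "symbol": symbol,
            "waveform": "sine",
            "period": wf.period,
            "mean": wf.mean,
            "amplitude": wf.amplitude,
            "phase": wf.phase,
        }
    if isinstance(wf, Table):
        return {
            "symbol": symbol,
            "waveform": "table",
            "times": list(wf.times),
            "values": list(wf.values),
        }
    raise TypeError(f"cannot serialise waveform {type(wf).__name__}")


def circuit_to_config(c: Circuit) -> dict:
    """Serialise a circuit back to a schema-1 config mapping."""
    cfg: dict = {"schema": SCHEMA_VERSION}
    if c.default_model:
        cfg["model"] = c.default_model
    if all(mid == c.default_model for mid in c.nodes.values()):
        cfg["nodes"] = list(c.nodes)
    else:
        cfg["nodes"] = dict(c.nodes)
    cfg["edges"] = [e.label() for e in c.edges if e.channel != "TWOINPUT"]
    if c.proteases:
        cfg["proteases"] = [
            {"name": p.name, "targets": p.targets, "kcat": p.kcat, "Km": p.Km, "conc": p.conc}
            for p in c.proteases
        ]
    if c.inducers:
        cfg["inducers"] = [
            {"name": i.name, "edge": i.edge.label(), "K": i.K, "conc": i.conc}
            for i in c.inducers
        ]
    if c.two_input_params:
        cfg["two_input"] = [
            {"target": t, "params": dict(p)} for t, p in c.two_input_params.items()
        ]
    params = dict(c.parameters)
    params.update({f"{sym}@{node}": v for (node, sym), v in c.node_parameters.items()})
    if params:
        cfg["parameters"] = params
    if c.initial_conditions:
        cfg["initial_conditions"] = {
            f"{role}@{node}": v for (node, role), v in c.initial_conditions.items()
        }
    if c.rules:
        cfg["rules"] = [_waveform_to_dict(r.symbol, r.waveform) for r in c.rules]
    return cfg


def save_config(c: Circuit, path) -> None:
    path = Path(path)
    cfg = circuit_to_config(c)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
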