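"""Human-readable model reports and graph exports."""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .circuit import CompiledModel

__all__ = ["model_report", "write_graphml", "write_dot"]


def model_report(model: CompiledModel, path=None) -> str:
    """Structured listing of species, parameters, reactions, rules and
    conserved totals; deterministic across runs for identical models."""
    lines = []
    lines.append("# Compiled model report")
    lines.append("")
    lines.append(
        f"{len(model.species)} species, {len(model.param_names)} parameters, "
        f"{len(model.reactions)} reactions"
    )
    lines.append("")
    lines.append("## Species (initial value, nM)")
    for sp, v in zip(model.species, model.init):
        lines.append(f"- {sp} = {v:g}")
    lines.append("")
    lines.append("## Parameters")
    for name, v in zip(model.param_names, model.param_values):
        lines.append(f"- {name} = {v:g}")
    lines.append("")
    lines.append("## Reactions")
    for rxn in model.reactions:
        reactants = " + ".join(
            f"{-c} {s}" if c != -1 else s for s, c in rxn.stoich.items() if c < 0
        ) or "0"
        products = " + ".join(
            f"{c} {s}" if c != 1 else s for s, c in rxn.stoich.items() if c > 0
        ) or "0"
        lines.append(f"- {rxn.name}: {reactants} -> {products}")
        lines.append(f"    rate = {rxn.rate_law}")
    if model.rules:
        lines.append("")
        lines.append("## Rules (time-varying parameters)")
        for r in model.rules:
            lines.append(f"- {r.symbol} follows {r.waveform!r}")
    if model.conserved:
        lines.append("")
        lines.append("## Conserved totals")
        for label, coeffs in model.conserved:
            expr = " + ".join(
                f"{c:g}*{s}" if c != 1 else s for s, c in coeffs.items()
            )
            lines.append(f"- {label}: {expr}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.DiGraph, path) -> None:
    """Minimal DOT writer (no external graphviz bindings required)."""
    lines = ["digraph circuit {"]
    for node, data in graph.nodes(data=True):
        shape = "ellipse" if data.get("kind") == "node" else "point"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v in graph.edges():
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
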