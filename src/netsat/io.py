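"""JSON/CSV serialization for architectures, marginal families, and reports.

Probabilities are serialized as exact rational strings ("1/4") by default so
that consistency checks survive a round trip unchanged; plain JSON numbers
are accepted on input and preserved as floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Any, Mapping

from .architectures import DirectedNetwork, Hypergraph
from .consistency import ConsistencyReport, EdgeMarginalFamily, JointDistribution
from .marginalization import StateSpace

__all__ = [
    "RunConfig",
    "dump_number",
    "parse_number",
    "architecture_to_dict",
    "architecture_from_dict",
    "network_from_dict",
    "family_to_dict",
    "family_from_dict",
    "report_to_dict",
    "load_json",
    "save_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-level reproducibility settings echoed into every artifact."""

    seed: int = 0
    n_samples: int = 10_000
    tolerances: Mapping[str, float] = field(
        default_factory=lambda: {"lp": 1e-9, "bp": 1e-10}
    )
    output_dir: str = "."
    log_level: str = "INFO"

    def stamp(self, payload: dict) -> dict:
        payload.setdefault("config", {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "tolerances": dict(self.tolerances),
        })
        return payload


def dump_number(x) -> Any:
    if isinstance(x, Rational) and not isinstance(x, int):
        f = Fraction(x)
        return f"{f.numerator}/{f.denominator}" if f.denominator != 1 else str(f.numerator)
    return float(x) if not isinstance(x, int) else x


def parse_number(s):
    if isinstance(s, str):
        return Fraction(s)
    if isinstance(s, int):
        return Fraction(s)
    return float(s)


def architecture_to_dict(h: Hypergraph) -> dict:
    return {
        "variables": sorted(h.variables),
        "edges": sorted(sorted(e) for e in h.edges),
    }


def architecture_from_dict(d: Mapping) -> Hypergraph:
    try:
        return Hypergraph(d["variables"], d["edges"])
    except KeyError as e:
        raise ValueError(
            f"architecture JSON must have 'variables' and 'edges' keys (missing {e})"
        ) from None


def network_from_dict(d: Mapping) -> DirectedNetwork:
    try:
        return DirectedNetwork(d["nodes"], d["arcs"], d["focal"])
    except KeyError as e:
        raise ValueError(
            f"network JSON must have 'nodes', 'arcs' and 'focal' keys (missing {e})"
        ) from None


def _state_key(st: tuple) -> str:
    return "".join(str(s) for s in st)


def _parse_state_key(key: str, levels: list[tuple]) -> tuple:
    toks = key.split(",") if "," in key else list(key)
    if len(toks) != len(levels):
        raise ValueError(f"state key '{key}' has wrong arity")
    out = []
    for tok, ls in zip(toks, levels):
        match = next((l for l in ls if str(l) == tok), None)
        if match is None:
            raise ValueError(f"state token '{tok}' not among levels {ls}")
        out.append(match)
    return tuple(out)


def family_to_dict(v: EdgeMarginalFamily) -> dict:
    space, h = v.space, v.architecture
    return {
        "architecture": {
            "variables": list(h.variables),
            "edges": [list(space.edge_variables(e)) for e in h.edges],
        },
        "levels": {
            var: list(space.levels_of(var)) for var in space.variables
        },
        "tables": {
            h.edge_label(ei): {
                _state_key(st): dump_number(p) for st, p in sorted(
                    v.tables[ei].items(), key=lambda kv: str(kv[0])
                )
            }
            for ei in range(len(h.edges))
        },
    }


def family_from_dict(d: Mapping) -> EdgeMarginalFamily:
    arch = d["architecture"]
    h = Hypergraph(arch["variables"], arch["edges"])
    space = StateSpace(
        h.variables, {v: tuple(ls) for v, ls in d["levels"].items()}
    )
    tables = []
    for ei in range(len(h.edges)):
        label = h.edge_label(ei)
        if label not in d["tables"]:
            raise ValueError(f"missing table for edge '{label}'")
        evars = space.edge_variables(h.edges[ei])
        lsets = [space.levels_of(v) for v in evars]
        table = {}
        for key, val in d["tables"][label].items():
            table[_parse_state_key(key, lsets)] = parse_number(val)
        tables.append(table)
    return EdgeMarginalFamily(h, space, tuple(tables))


def joint_to_dict(j: JointDistribution) -> dict:
    return {
        "variables": list(j.space.variables),
        "weights": {
            _state_key(st): dump_number(w)
            for st, w in zip(j.space.joint_states(), j.weights)
            if w != 0
        },
    }


def report_to_dict(r: ConsistencyReport) -> dict:
    return {
        "local": r.local,
        "global": r.global_,
        "witness": joint_to_dict(r.witness) if r.witness is not None else None,
        "violated": list(r.violated),
    }


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
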