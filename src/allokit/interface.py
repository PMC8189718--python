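"""File formats and seeded fixture generation.

Graphs, ensembles, targets and landscapes travel as small JSON documents;
curves and tables as CSV. Subsets are serialized as sorted site lists
("2,4,6"), intrinsic-HOC keys as "i|S" strings, and vertices of built
allostery graphs as "conformation|sites". Floats round-trip exactly
(shortest-repr JSON), so read(write(A)) reproduces A bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from .allostery import (
    AllosteryGraph,
    ConformationTable,
    HorizontalSpec,
    Subset,
    subsets,
)
from .flexibility import TargetPattern
from .graphcore import EquilibriumGraph
from .homeasures import FreeEnergyLandscape

__all__ = [
    "FixtureSpec",
    "random_ensemble",
    "write_ensemble",
    "read_ensemble",
    "write_graph",
    "read_graph",
    "read_targets",
    "write_targets",
    "read_landscape",
    "roundtrip",
]


def _subset_str(S) -> str:
    return ",".join(map(str, sorted(S)))


def _parse_subset(s: str) -> Subset:
    return frozenset(int(t) for t in s.split(",") if t)


class SchemaError(ValueError):
    """A document violates the expected layout."""


# ---------------------------------------------------------------- ensembles


def ensemble_to_dict(A: AllosteryGraph) -> dict:
    return {
        "n": A.n,
        "conformations": [
            {
                "id": c,
                "K_bare": [
                    math.exp(A.table.log_K_bare[(c, i)]) for i in range(1, A.n + 1)
                ],
                "omega": {
                    f"{i}|{_subset_str(S)}": math.exp(lo)
                    for (cc, i, S), lo in sorted(
                        A.table.log_omega.items(), key=lambda kv: repr(kv[0])
                    )
                    if cc == c
                },
            }
            for c in A.conformations
        ],
        "lambda": {c: math.exp(A.horiz.log_lambda[c]) for c in A.conformations},
    }


def ensemble_from_dict(doc: dict) -> AllosteryGraph:
    try:
        n = int(doc["n"])
        confs = [c["id"] for c in doc["conformations"]]
        log_K_bare = {}
        log_omega = {}
        for c in doc["conformations"]:
            if len(c["K_bare"]) != n:
                raise SchemaError(
                    f"conformation {c['id']!r}: expected {n} bare constants"
                )
            for i, K in enumerate(c["K_bare"], start=1):
                if not K > 0:
                    raise SchemaError(
                        f"conformation {c['id']!r}, site {i}: K must be positive, got {K}"
                    )
                log_K_bare[(c["id"], i)] = math.log(K)
            for key, w in c.get("omega", {}).items():
                i_str, S_str = key.split("|")
                if not w > 0:
                    raise SchemaError(
                        f"conformation {c['id']!r}, omega {key!r}: must be positive"
                    )
                log_omega[(c["id"], int(i_str), _parse_subset(S_str))] = math.log(w)
        log_lambda = {}
        for c, lam in doc["lambda"].items():
            if not lam > 0:
                raise SchemaError(f"lambda[{c!r}] must be positive, got {lam}")
            log_lambda[c] = math.log(lam)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed ensemble document: {exc}") from exc
    table = ConformationTable(
        n=n, conformations=confs, log_K_bare=log_K_bare, log_omega=log_omega
    )
    horiz = HorizontalSpec(conformations=confs, log_lambda=log_lambda)
    return AllosteryGraph(n=n, table=table, horiz=horiz)


def write_ensemble(A: AllosteryGraph, path) -> None:
    Path(path).write_text(json.dumps(ensemble_to_dict(A), indent=1))


def read_ensemble(path) -> AllosteryGraph:
    return ensemble_from_dict(json.loads(Path(path).read_text()))


def roundtrip(path) -> AllosteryGraph:
    """Read an ensemble, check it re-serializes identically, return it."""
    doc = json.loads(Path(path).read_text())
    A = ensemble_from_dict(doc)
    if ensemble_to_dict(A) != doc:
        raise SchemaError("ensemble does not survive a serialization round trip")
    return A


# ------------------------------------------------------------------- graphs


def vertex_str(v) -> str:
    if isinstance(v, tuple) and len(v) == 2 and isinstance(v[1], int):
        c, mask = v
        sites = [i + 1 for i in range(mask.bit_length()) if mask >> i & 1]
        return f"{c}|{_subset_str(sites)}"
    return str(v)


def write_graph(eg: EquilibriumGraph, path) -> None:
    """Equilibrium graph as JSON; reverse edges are implied."""
    edges = []
    seen = set()
    for (i, j), ll in eg.log_labels.items():
        if (j, i) in seen:
            continue
        seen.add((i, j))
        edges.append(
            {"from": vertex_str(i), "to": vertex_str(j), "label": math.exp(ll)}
        )
    doc = {
        "vertices": [vertex_str(v) for v in eg.vertices],
        "edges": edges,
        "reference": vertex_str(eg.reference),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_graph(path) -> EquilibriumGraph:
    doc = json.loads(Path(path).read_text())
    try:
        log_labels = {}
        for e in doc["edges"]:
            if not e["label"] > 0:
                raise SchemaError(f"edge {e['from']}->{e['to']}: label must be positive")
            ll = math.log(e["label"])
            log_labels[(e["from"], e["to"])] = ll
            log_labels[(e["to"], e["from"])] = -ll
        return EquilibriumGraph(
            vertices=list(doc["vertices"]),
            log_labels=log_labels,
            reference=doc.get("reference", doc["vertices"][0]),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed graph document: {exc}") from exc


# ------------------------------------------------------------------ targets


def read_targets(path) -> TargetPattern:
    doc = json.loads(Path(path).read_text())
    beta = {int(i): float(v) for i, v in doc["beta"].items()}
    alpha = {}
    for key, v in doc["alpha"].items():
        i_str, S_str = key.split("|")
        alpha[(int(i_str), _parse_subset(S_str))] = float(v)
    return TargetPattern(n=int(doc["n"]), beta=beta, alpha=alpha)


def write_targets(t: TargetPattern, path) -> None:
    doc = {
        "n": t.n,
        "beta": {str(i): v for i, v in sorted(t.beta.items())},
        "alpha": {
            f"{i}|{_subset_str(S)}": v
            for (i, S), v in sorted(t.alpha.items(), key=lambda kv: repr(kv[0]))
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------- landscapes


def read_landscape(path) -> FreeEnergyLandscape:
    doc = json.loads(Path(path).read_text())
    DeltaPhi = {
        _parse_subset(key): float(v) for key, v in doc["DeltaPhi"].items()
    }
    return FreeEnergyLandscape(n=int(doc["n"]), DeltaPhi=DeltaPhi)


# ----------------------------------------------------------------- fixtures


@dataclass
class FixtureSpec:
    """Reproducible random-ensemble recipe (log-uniform draws)."""

    n: int
    N: int
    k_range: Tuple[float, float] = (1e-2, 1e2)
    lam_range: Tuple[float, float] = (1e-3, 1e3)
    omega_mode: str = "independent"  # or "random"
    omega_range: Tuple[float, float] = (1e-1, 1e1)
    seed: int = 0


def random_ensemble(spec: FixtureSpec) -> AllosteryGraph:
    """Log-uniform random ensemble; the same spec always yields the same one."""
    rng = np.random.default_rng(spec.seed)
    confs = [f"c{k + 1}" for k in range(spec.N)]
    lo, hi = map(math.log, spec.k_range)
    log_K_bare = {
        (c, i): float(rng.uniform(lo, hi))
        for c in confs
        for i in range(1, spec.n + 1)
    }
    log_omega = {}
    if spec.omega_mode == "random":
        wlo, whi = map(math.log, spec.omega_range)
        for c in confs:
            for S in subsets(spec.n):
                if not S:
                    continue
                for i in range(1, min(S)):
                    log_omega[(c, i, S)] = float(rng.uniform(wlo, whi))
    elif spec.omega_mode != "independent":
        raise ValueError(f"unknown omega mode {spec.omega_mode!r}")
    llo, lhi = map(math.log, spec.lam_range)
    log_lambda = {confs[0]: 0.0}
    for c in confs[1:]:
        log_lambda[c] = float(rng.uniform(llo, lhi))
    table = ConformationTable(
        n=spec.n, conformations=confs, log_K_bare=log_K_bare, log_omega=log_omega
    )
    horiz = HorizontalSpec(conformations=confs, log_lambda=log_lambda)
    return AllosteryGraph(n=spec.n, table=table, horiz=horiz)
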