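"""Reading and writing community parameters, assembly maps and provenance.

CommunityParameters round-trip through JSON or through a pair of CSVs (a
vector table ``species, r, s, K_T, f`` and a square interaction matrix with
species names as header row and column).  Assembly maps serialize to JSON
(nodes as sorted species-name lists) and to an edge-list CSV, with optional
GraphML export.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import AssemblyMap, members_of
from .params import CommunityParameters

__all__ = [
    "read_parameters_json",
    "write_parameters_json",
    "read_parameters_csv",
    "write_parameters_csv",
    "read_parameters",
    "write_map_json",
    "write_map_edgelist",
    "write_map_graphml",
    "config_hash",
]


class FileFormatError(ValueError):
    """Raised for malformed parameter files, naming the offending field."""


def write_parameters_json(params: CommunityParameters, path) -> None:
    payload = {
        "names": list(params.names),
        "r": params.r.tolist(),
        "s": params.s.tolist(),
        "A": params.A.tolist(),
        "K_T": params.K_T,
        "f": params.f,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_parameters_json(path) -> CommunityParameters:
    payload = json.loads(Path(path).read_text())
    for key in ("names", "r", "s", "A"):
        if key not in payload:
            raise FileFormatError(f"parameter JSON is missing field {key!r}")
    A = np.asarray(payload["A"], dtype=float)
    _check_matrix(A, payload["names"])
    return CommunityParameters(
        r=np.asarray(payload["r"], dtype=float),
        s=np.asarray(payload["s"], dtype=float),
        A=A,
        K_T=float(payload.get("K_T", 10_000.0)),
        f=float(payload.get("f", 0.0)),
        names=tuple(payload["names"]),
    )


def _check_matrix(A: np.ndarray, names) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise FileFormatError(f"interaction matrix is not square: shape {A.shape}")
    if len(names) != A.shape[0]:
        raise FileFormatError(f"{len(names)} species names for a {A.shape[0]}x{A.shape[1]} matrix")
    for i in range(A.shape[0]):
        if A[i, i] != 0:
            raise FileFormatError(
                f"nonzero diagonal at cell ({names[i]}, {names[i]}): {A[i, i]}"
            )


def write_parameters_csv(params: CommunityParameters, vector_path, matrix_path) -> None:
    vec = pd.DataFrame(
        {
            "species": list(params.names),
            "r": params.r,
            "s": params.s,
            "K_T": params.K_T,
            "f": params.f,
        }
    )
    vec.to_csv(vector_path, index=False)
    mat = pd.DataFrame(params.A, index=list(params.names), columns=list(params.names))
    mat.to_csv(matrix_path, index_label="species")


def read_parameters_csv(vector_path, matrix_path) -> CommunityParameters:
    vec = pd.read_csv(vector_path)
    for col in ("species", "r", "s"):
        if col not in vec.columns:
            raise FileFormatError(f"vector CSV is missing column {col!r}")
    names = [str(n) for n in vec["species"]]
    mat = pd.read_csv(matrix_path, index_col=0)
    mat.index = [str(i) for i in mat.index]
    mat.columns = [str(c) for c in mat.columns]
    if list(mat.index) != names or list(mat.columns) != names:
        raise FileFormatError("matrix CSV species ordering does not match the vector CSV")
    A = mat.to_numpy(dtype=float)
    _check_matrix(A, names)
    return CommunityParameters(
        r=vec["r"].to_numpy(dtype=float),
        s=vec["s"].to_numpy(dtype=float),
        A=A,
        K_T=float(vec["K_T"].iloc[0]) if "K_T" in vec.columns else 10_000.0,
        f=float(vec["f"].iloc[0]) if "f" in vec.columns else 0.0,
        names=tuple(names),
    )


def read_parameters(path) -> CommunityParameters:
    """Dispatch on extension: ``.json`` or a vector CSV with a sibling
    ``<stem>_matrix.csv``."""
    path = Path(path)
    if path.suffix == ".json":
        return read_parameters_json(path)
    return read_parameters_csv(path, path.with_name(path.stem + "_matrix.csv"))


def write_parameters(params: CommunityParameters, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        write_parameters_json(params, path)
    else:
        write_parameters_csv(params, path, path.with_name(path.stem + "_matrix.csv"))


# ---------------------------------------------------------------------------
# assembly maps


def _node_names(mask: int, names) -> list[str]:
    return [names[i] for i in members_of(mask)]


def write_map_json(amap: AssemblyMap, params: CommunityParameters, path) -> None:
    payload = {
        "species": list(params.names),
        "climax": _node_names(amap.climax, params.names),
        "consortium_size": amap.consortium_size,
        "nodes": [
            {
                "members": _node_names(mask, params.names),
                "abundances": amap.nodes[mask].abundances.tolist(),
                "at_cap": bool(amap.nodes[mask].at_cap),
            }
            for mask in sorted(amap.nodes)
        ],
        "edges": [
            {
                "source": _node_names(e.source, params.names),
                "target": _node_names(e.target, params.names),
                "arrivals": [params.names[i] for i in sorted(e.arrivals)],
                "category": e.category,
            }
            for e in amap.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_map_json(path) -> tuple[AssemblyMap, list[str]]:
    """Rebuild an assembly map (nodes, equilibria, edges) from its JSON form."""
    from .params import EquilibriumResult

    payload = json.loads(Path(path).read_text())
    names = payload["species"]
    index = {n: i for i, n in enumerate(names)}
    S = len(names)

    def mask(members: list[str]) -> int:
        m = 0
        for name in members:
            m |= 1 << index[name]
        return m

    nodes = {}
    for node in payload["nodes"]:
        m = mask(node["members"])
        nodes[m] = EquilibriumResult(
            subset=frozenset(index[n] for n in node["members"]),
            abundances=np.asarray(node["abundances"], dtype=float),
            feasible=True,
            stable=True,
            at_cap=bool(node.get("at_cap", False)),
        )
    from .assembly import AssemblyEdge

    edges = [
        AssemblyEdge(
            source=mask(e["source"]),
            target=mask(e["target"]),
            arrivals=frozenset(index[n] for n in e["arrivals"]),
            category=e["category"],
        )
        for e in payload["edges"]
    ]
    amap = AssemblyMap(
        S=S,
        climax=mask(payload["climax"]),
        nodes=nodes,
        edges=edges,
        consortium_size=int(payload.get("consortium_size", 1)),
    )
    return amap, names


def write_map_edgelist(amap: AssemblyMap, params: CommunityParameters, path) -> None:
    rows = [
        {
            "source": "+".join(_node_names(e.source, params.names)) or "(empty)",
            "target": "+".join(_node_names(e.target, params.names)) or "(empty)",
            "arrivals": "+".join(params.names[i] for i in sorted(e.arrivals)),
            "category": e.category,
        }
        for e in amap.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "arrivals", "category"]).to_csv(path, index=False)


def write_map_graphml(amap: AssemblyMap, params: CommunityParameters, path) -> None:
    g = nx.MultiDiGraph()
    for mask in amap.nodes:
        g.add_node("+".join(_node_names(mask, params.names)) or "(empty)", size=bin(mask).count("1"))
    for e in amap.edges:
        g.add_edge(
            "+".join(_node_names(e.source, params.names)) or "(empty)",
            "+".join(_node_names(e.target, params.names)) or "(empty)",
            arrivals="+".join(params.names[i] for i in sorted(e.arrivals)),
            category=e.category,
        )
    nx.write_graphml(g, path)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance records."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
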