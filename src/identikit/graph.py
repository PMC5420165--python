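"""Identifiability-annotated network export for Cytoscape.

The model structure is reduced to four boolean structural Jacobians —
states vs states (df/dx), observables vs states (dg/dx), states vs inputs
(df/du) and states vs parameters (df/dtheta) — evaluated symbolically and
thresholded at identically-zero.  Each nonzero entry becomes a directed
edge from the dependency to the dependent node (x2 -> x1 when x2 appears in
the equation of x1).  Parameter nodes carry the identifiable flag from the
largest-subset analysis; highly-collinear parameter pairs are joined by
undirected edges, and minimal collinear groups appear as G{size}({index})
group nodes with undirected membership edges.  Output formats are GraphML
(primary) and SIF plus attribute tables (secondary), both readable by
Cytoscape.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import sympy as sp

from .collinearity import NormalizedSensitivityMatrix, collinearity_index
from .enumeration import CollinearityGroup
from .model import KineticModel

NODE_KINDS = ("state", "parameter", "observable", "input", "group")
EDGE_KINDS = ("influence", "observation", "collinearity", "membership")
_SIF_INTERACTION = {"influence": "influences", "observation": "observes",
                    "collinearity": "collinear", "membership": "member"}


@dataclass(frozen=True)
class GraphNode:
    id: str
    kind: str
    identifiable: bool | None = None    # parameters only
    ci: float | None = None             # group nodes only


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    kind: str

    @property
    def directed(self) -> bool:
        return self.kind in ("influence", "observation")


@dataclass
class IdentifiabilityGraph:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    def node_set(self) -> set[GraphNode]:
        return set(self.nodes)

    def edge_set(self) -> set[GraphEdge]:
        """Edges as a set; undirected edges are canonicalized by endpoint order."""
        out = set()
        for e in self.edges:
            if e.directed or e.source <= e.target:
                out.add(e)
            else:
                out.add(GraphEdge(e.target, e.source, e.kind))
        return out

    def __eq__(self, other):
        return (self.node_set() == other.node_set()
                and self.edge_set() == other.edge_set())


def structural_jacobians(model: KineticModel) -> dict[str, np.ndarray]:
    """Boolean structural Jacobians ss, so, si, sp.

    An entry is True iff the symbolic partial derivative is not identically
    zero (after simplification, so cancelling terms such as theta*x - theta*x
    count as structurally zero).
    """
    syms = model.symbols()
    x = [syms[n] for n in model.state_names]
    th = [syms[n] for n in model.param_names]
    u = [syms[n] for n in model.input_names]

    def nonzero(exprs, wrt):
        out = np.zeros((len(exprs), len(wrt)), dtype=bool)
        for i, e in enumerate(exprs):
            for j, s in enumerate(wrt):
                d = sp.diff(e, s)
                if d != 0 and sp.simplify(d) != 0:
                    out[i, j] = True
        return out

    return {
        "ss": nonzero(model.rhs_exprs, x),
        "so": nonzero(model.obs_exprs, x),
        "si": nonzero(model.rhs_exprs, u),
        "sp": nonzero(model.rhs_exprs, th),
        "op": nonzero(model.obs_exprs, th),   # parameters in observation functions
    }


def numeric_structural_jacobians(model: KineticModel, seed: int = 0,
                                 n_probes: int = 5, tol: float = 1e-12
                                 ) -> dict[str, np.ndarray]:
    """Numeric fallback: probe partials at random points (heuristic)."""
    rng = np.random.default_rng(seed)
    jac = model.jacobians()
    shapes = {"ss": (model.n_states, model.n_states),
              "so": (model.n_obs, model.n_states),
              "si": (model.n_states, len(model.input_names)),
              "sp": (model.n_states, model.n_params),
              "op": (model.n_obs, model.n_params)}
    keys = {"ss": "dfdx", "so": "dgdx", "sp": "dfdp", "op": "dgdp"}
    out = {k: np.zeros(s, dtype=bool) for k, s in shapes.items()}
    lb, ub = model.bounds.T
    for _ in range(n_probes):
        x = rng.uniform(0.1, 2.0, model.n_states)
        th = rng.uniform(lb, np.minimum(ub, lb + 10 * np.maximum(lb, 1.0)))
        u = rng.uniform(0.1, 2.0, len(model.input_names))
        for k, jk in keys.items():
            m = np.abs(np.asarray(jac[jk](list(x), list(th), list(u)),
                                  dtype=float).reshape(shapes[k]))
            out[k] |= m > tol
        if model.input_names:
            m = np.abs(np.asarray(jac["dfdu"](list(x), list(th), list(u)),
                                  dtype=float).reshape(shapes["si"]))
            out["si"] |= m > tol
    return out


def build_graph(model: KineticModel, jacobians: dict[str, np.ndarray],
                identifiable_subset, nsm: NormalizedSensitivityMatrix | None = None,
                groups: list[CollinearityGroup] | None = None,
                ci_threshold: float = 20.0,
                analysed_params: list[str] | None = None) -> IdentifiabilityGraph:
    """Assemble the typed network.

    Edge direction is dependency -> dependent: a nonzero df_i/dz_j entry
    produces the edge z_j -> x_i, and a nonzero dg_i/dx_j entry produces
    x_j -> y_i.  Parameters are flagged identifiable iff they belong to
    ``identifiable_subset``; undirected collinearity edges connect pairs
    whose CI (from ``nsm``) reaches the threshold; groups become GX(Y)
    nodes with undirected membership edges.
    """
    identifiable = set(identifiable_subset or ())
    params = list(analysed_params) if analysed_params is not None else list(model.param_names)
    unknown = identifiable - set(params)
    if unknown:
        raise KeyError(f"identifiable subset references unknown parameters {sorted(unknown)}")

    g = IdentifiabilityGraph()
    for s in model.state_names:
        g.nodes.append(GraphNode(s, "state"))
    for p in params:
        g.nodes.append(GraphNode(p, "parameter", identifiable=p in identifiable))
    for o in model.obs_names:
        g.nodes.append(GraphNode(o, "observable"))
    for u in model.input_names:
        g.nodes.append(GraphNode(u, "input"))

    J = jacobians
    for i, si in enumerate(model.state_names):
        for j, sj in enumerate(model.state_names):
            if J["ss"][i, j]:
                g.edges.append(GraphEdge(sj, si, "influence"))
        for j, pj in enumerate(model.param_names):
            if J["sp"][i, j] and pj in params:
                g.edges.append(GraphEdge(pj, si, "influence"))
        for j, uj in enumerate(model.input_names):
            if J["si"][i, j]:
                g.edges.append(GraphEdge(uj, si, "influence"))
    for i, oi in enumerate(model.obs_names):
        for j, sj in enumerate(model.state_names):
            if J["so"][i, j]:
                g.edges.append(GraphEdge(sj, oi, "observation"))
        if "op" in J:
            for j, pj in enumerate(model.param_names):
                if J["op"][i, j] and pj in params:
                    g.edges.append(GraphEdge(pj, oi, "influence"))

    if nsm is not None:
        names = [p for p in nsm.param_names if p in set(params)]
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ps = collinearity_index(nsm, (names[a], names[b]))
                if ps.ci >= ci_threshold:
                    g.edges.append(GraphEdge(names[a], names[b], "collinearity"))

    for grp in groups or []:
        g.nodes.append(GraphNode(grp.label, "group", ci=grp.ci))
        for m in grp.members:
            g.edges.append(GraphEdge(grp.label, m, "membership"))
    return g


# -- serialization ---------------------------------------------------------

def _to_networkx(graph: IdentifiabilityGraph) -> nx.MultiDiGraph:
    G = nx.MultiDiGraph()
    for n in graph.nodes:
        attrs = {"kind": n.kind}
        if n.identifiable is not None:
            attrs["identifiable"] = bool(n.identifiable)
        if n.ci is not None:
            attrs["ci"] = float(n.ci)
        G.add_node(n.id, **attrs)
    for e in graph.edges:
        G.add_edge(e.source, e.target, kind=e.kind, directed=e.directed)
    return G


def write_graphml(graph: IdentifiabilityGraph, path) -> None:
    nx.write_graphml(_to_networkx(graph), path)


def read_graphml(path) -> IdentifiabilityGraph:
    G = nx.read_graphml(path)
    g = IdentifiabilityGraph()
    for nid, attrs in G.nodes(data=True):
        g.nodes.append(GraphNode(
            nid, attrs["kind"],
            identifiable=attrs.get("identifiable"),
            ci=attrs.get("ci")))
    for s, t, attrs in G.edges(data=True):
        g.edges.append(GraphEdge(s, t, attrs["kind"]))
    return g


def write_sif(graph: IdentifiabilityGraph, path) -> list[Path]:
    """SIF edge list plus node- and edge-attribute CSV tables.

    SIF lines are ``source interaction target`` with interaction in
    {influences, observes, collinear, member}.
    """
    path = Path(path)
    sif = path.with_suffix(".sif")
    nodes_csv = path.with_suffix(".nodes.csv")
    edges_csv = path.with_suffix(".edges.csv")
    with open(sif, "w") as fh:
        connected = set()
        for e in graph.edges:
            fh.write(f"{e.source} {_SIF_INTERACTION[e.kind]} {e.target}\n")
            connected |= {e.source, e.target}
        for n in graph.nodes:       # isolated nodes: bare id lines
            if n.id not in connected:
                fh.write(f"{n.id}\n")
    with open(nodes_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "kind", "identifiable", "ci"])
        for n in graph.nodes:
            w.writerow([n.id, n.kind,
                        "" if n.identifiable is None else n.identifiable,
                        "" if n.ci is None else n.ci])
    with open(edges_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "kind", "directed"])
        for e in graph.edges:
            w.writerow([e.source, e.target, e.kind, e.directed])
    return [sif, nodes_csv, edges_csv]


def write_graph(graph: IdentifiabilityGraph, path, fmt: str = "graphml"):
    """Serialize as GraphML or SIF+attribute tables (Cytoscape-ready)."""
    if fmt == "graphml":
        write_graphml(graph, path)
        return [Path(path)]
    if fmt == "sif":
        return write_sif(graph, path)
    raise ValueError(f"unknown graph format {fmt!r}")
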