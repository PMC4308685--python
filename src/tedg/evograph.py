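"""Ordering-network construction, deconvolution and backbone extraction.

The pipeline runs in four stages:

1. per-patient *sequential networks*: lesion A -> B whenever A first
   becomes detectable (MCF above threshold) strictly earlier than B;
2. the *Integrated Sequential Network* (ISN): edges pooled across
   patients, weighted by the number of supporting patients;
3. *simplification* (reciprocal 2-cycles reduced by subtracting the
   weaker direction) followed by *network deconvolution*,
   ``G_dir = G_obs (I + beta * G_obs)^-1``, which down-weights orders
   explained by transitivity;
4. the *TEDG backbone*: edge costs ``exp(-w_deconvolved)``, minimum
   spanning tree (Prim on the undirected projection, re-oriented) or a
   minimum spanning arborescence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from tedg.mcf_adjust import MCFProfile

logger = logging.getLogger(__name__)

ROLES = ("sequential", "ISN", "simplified", "deconvolved", "tedg")


class OrderGraph(nx.DiGraph):
    """Directed lesion-ordering graph.

    A thin :class:`networkx.DiGraph` whose graph attribute ``role``
    records the pipeline stage (sequential, ISN, simplified,
    deconvolved, tedg).  Nodes carry ``recurrence`` (number of patients
    ever showing the lesion); edges carry ``weight`` and, through the
    ISN stage, the ``patients`` supporting them.
    """

    def __init__(self, incoming_graph_data=None, role: str = "sequential",
                 **attr) -> None:
        super().__init__(incoming_graph_data, **attr)
        self.graph.setdefault("role", role)

    @property
    def role(self) -> str:
        return self.graph["role"]


@dataclass
class TedgConfig:
    """Pipeline parameters.

    beta : deconvolution strength in (0, 1); 0.2 by default.
    presence_threshold : MCF above which a lesion is called present
        (strict inequality); 0.05 = 5% of leukemic cells.
    tree_method : "undirected_prim" or "arborescence".
    """

    beta: float = 0.2
    presence_threshold: float = 0.05
    tree_method: str = "undirected_prim"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not 0.0 < self.presence_threshold < 1.0:
            raise ValueError("presence_threshold must be in (0, 1)")
        if self.tree_method not in ("undirected_prim", "arborescence"):
            raise ValueError(
                f"unknown tree_method {self.tree_method!r}")


def presence_calls(profile: MCFProfile, threshold: float = 0.05
                   ) -> dict[str, bool]:
    """Call each lesion present iff its MCF strictly exceeds threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return {lesion: mcf > threshold for lesion, mcf in profile.mcf.items()}


def build_sequential_network(profiles: list[MCFProfile],
                             threshold: float = 0.05) -> OrderGraph:
    """Per-patient sequential network from time-ordered MCF profiles.

    For each lesion ever called present, its first-presence time is the
    earliest sample at which it exceeds the threshold.  A -> B is added
    whenever first(A) < first(B); ties get no edge; lesions never
    present are excluded.  A lesion that later disappears keeps its
    original first-presence time.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 time points to order lesions")
    pids = {p.patient_id for p in profiles}
    if len(pids) > 1:
        raise ValueError(f"profiles span multiple patients: {pids}")
    patient_id = next(iter(pids))
    profiles = sorted(profiles, key=lambda p: p.sample_time)

    first_time: dict[str, float] = {}
    for prof in profiles:
        for lesion, present in presence_calls(prof, threshold).items():
            if present and lesion not in first_time:
                first_time[lesion] = prof.sample_time

    g = OrderGraph(role="sequential")
    g.graph["patient_id"] = patient_id
    for lesion in first_time:
        g.add_node(lesion, recurrence=1)
    for a, ta in first_time.items():
        for b, tb in first_time.items():
            if ta < tb:
                g.add_edge(a, b, weight=1,
                           patients=frozenset({patient_id}))
    return g


def pool_isn(networks: list[OrderGraph]) -> OrderGraph:
    """Pool per-patient sequential networks into the ISN.

    Edge weight = number of patients whose sequential network contains
    the edge; node recurrence = number of patients in which the lesion
    is ever present.
    """
    for g in networks:
        if g.role != "sequential":
            raise ValueError(f"expected sequential networks, got {g.role!r}")
    isn = OrderGraph(role="ISN")
    for g in networks:
        pid = g.graph.get("patient_id", "?")
        for n in g.nodes:
            if n in isn:
                isn.nodes[n]["recurrence"] += 1
            else:
                isn.add_node(n, recurrence=1)
        for u, v in g.edges:
            if isn.has_edge(u, v):
                isn[u][v]["weight"] += 1
                isn[u][v]["patients"] = isn[u][v]["patients"] | {pid}
            else:
                isn.add_edge(u, v, weight=1, patients=frozenset({pid}))
    return isn


def simplify_isn(isn: OrderGraph) -> OrderGraph:
    """Reduce reciprocal edge pairs to their net direction.

    For each 2-cycle (A->B weight w1, B->A weight w2) only the heavier
    direction survives, with weight |w1 - w2|; equal weights cancel.
    Self-loops are dropped defensively.
    """
    if isn.role != "ISN":
        raise ValueError(f"expected an ISN, got role {isn.role!r}")
    g = OrderGraph(role="simplified")
    for n, d in isn.nodes(data=True):
        g.add_node(n, **d)
    done: set[frozenset] = set()
    for u, v, d in isn.edges(data=True):
        if u == v:
            continue
        pair = frozenset((u, v))
        if pair in done:
            continue
        done.add(pair)
        w_uv = d["weight"]
        if isn.has_edge(v, u):
            w_vu = isn[v][u]["weight"]
            if w_uv == w_vu:
                continue
            if w_uv > w_vu:
                g.add_edge(u, v, weight=w_uv - w_vu,
                           patients=d.get("patients", frozenset()))
            else:
                g.add_edge(v, u, weight=w_vu - w_uv,
                           patients=isn[v][u].get("patients", frozenset()))
        else:
            g.add_edge(u, v, weight=w_uv,
                       patients=d.get("patients", frozenset()))
    return g


def deconvolve(g: OrderGraph, beta: float = 0.2,
               drop_below: float = 1e-9) -> OrderGraph:
    """Remove indirect (transitive) order contributions.

    Builds the weighted adjacency ``G_obs`` over the sorted node list and
    returns the graph of ``G_dir = G_obs (I + beta * G_obs)^-1``.
    Entries below ``drop_below`` (including all negatives) are treated
    as non-direct and dropped.  Results are invariant to node
    permutation.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    g_obs = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        g_obs[idx[u], idx[v]] = d["weight"]
    m = np.eye(n) + beta * g_obs
    if n and abs(np.linalg.det(m)) < 1e-12:
        raise np.linalg.LinAlgError(
            "I + beta*G_obs is singular; retry with a smaller beta")
    g_dir = g_obs @ np.linalg.inv(m)

    out = OrderGraph(role="deconvolved")
    for node in nodes:
        out.add_node(node, **g.nodes[node])
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i != j and g_dir[i, j] >= drop_below:
                out.add_edge(u, v, weight=float(g_dir[i, j]))
    return out


def extract_tedg(g: OrderGraph, method: str = "undirected_prim"
                 ) -> OrderGraph:
    """Extract the spanning-tree backbone of a deconvolved graph.

    Edge costs are ``exp(-w)``, so the minimum spanning tree keeps the
    strongest direct orders.  ``undirected_prim`` runs Prim's algorithm
    on the undirected projection (reciprocal costs resolved by the
    cheaper direction) and re-orients each tree edge by the surviving
    directed edge; ``arborescence`` computes a minimum-cost spanning
    arborescence rooted at the node with maximal out-minus-in weighted
    degree.  Disconnected inputs are handled per weakly-connected
    component; the result is acyclic with <= n - 1 edges.
    """
    if method not in ("undirected_prim", "arborescence"):
        raise ValueError(f"unknown tree method {method!r}")
    tree = OrderGraph(role="tedg")
    for n, d in g.nodes(data=True):
        tree.add_node(n, **d)
    if g.number_of_edges() == 0:
        return tree

    if method == "undirected_prim":
        und = nx.Graph()
        und.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            cost = math.exp(-d["weight"])
            if not und.has_edge(u, v) or cost < und[u][v]["cost"]:
                und.add_edge(u, v, cost=cost)
        mst = nx.minimum_spanning_tree(und, weight="cost",
                                       algorithm="prim")
        for u, v in mst.edges:
            if g.has_edge(u, v) and g.has_edge(v, u):
                # keep the heavier (cheaper-cost) surviving direction
                if g[u][v]["weight"] >= g[v][u]["weight"]:
                    tree.add_edge(u, v, weight=g[u][v]["weight"])
                else:
                    tree.add_edge(v, u, weight=g[v][u]["weight"])
            elif g.has_edge(u, v):
                tree.add_edge(u, v, weight=g[u][v]["weight"])
            else:
                tree.add_edge(v, u, weight=g[v][u]["weight"])
    else:
        for comp in nx.weakly_connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_edges() == 0:
                continue
            root = max(
                sorted(sub.nodes),
                key=lambda v: (sub.out_degree(v, weight="weight")
                               - sub.in_degree(v, weight="weight")))
            pruned = nx.DiGraph()
            pruned.add_nodes_from(sub.nodes)
            for u, v, d in sub.edges(data=True):
                if v == root:
                    continue
                pruned.add_edge(u, v, cost=math.exp(-d["weight"]),
                                weight=d["weight"])
            try:
                arb = nx.minimum_spanning_arborescence(
                    pruned, attr="cost", preserve_attrs=True)
            except nx.NetworkXException:
                logger.warning(
                    "no spanning arborescence from root %r; "
                    "falling back to a branching", root)
                arb = nx.maximum_branching(
                    pruned, attr="weight", preserve_attrs=True)
            for u, v, d in arb.edges(data=True):
                tree.add_edge(u, v, weight=d["weight"])

    if not nx.is_directed_acyclic_graph(tree):
        raise RuntimeError("extracted backbone is not acyclic")
    return tree


def run_pipeline(patient_profiles: dict[str, list[MCFProfile]],
                 config: TedgConfig | None = None
                 ) -> dict[str, OrderGraph]:
    """Full pipeline: sequential networks -> ISN -> simplified ->
    deconvolved -> TEDG.

    ``patient_profiles`` maps patient_id to that patient's time-ordered
    MCF profiles.  Patients with fewer than two time points are skipped
    with a warning.  Returns the intermediate and final graphs keyed by
    role.
    """
    cfg = config or TedgConfig()
    networks = []
    for pid, profiles in sorted(patient_profiles.items()):
        if len({p.sample_time for p in profiles}) < 2:
            logger.warning("patient %s skipped: <2 time points", pid)
            continue
        networks.append(
            build_sequential_network(profiles, cfg.presence_threshold))
    isn = pool_isn(networks)
    simplified = simplify_isn(isn)
    dec = deconvolve(simplified, cfg.beta)
    tedg = extract_tedg(dec, cfg.tree_method)
    return {"ISN": isn, "simplified": simplified,
            "deconvolved": dec, "tedg": tedg}
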