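"""Residue-level dynamic coupling networks.

Residues are nodes anchored at their Cα atoms; edges join residue pairs in
persistent contact (minimum heavy-atom distance ≤ 5 Å in ≥ 75% of frames)
and carry

* the normalized fluctuation covariance C_ij (Pearson correlation of Cα
  displacement vectors, |C| ≤ 1),
* the coupling-path weight w_ij = −log|C_ij|,
* the mutual information M_ij estimated via Gaussian-mixture densities, and
* the conductance A_ij = |C_ij|·M_ij used for information-flow analysis.

On this graph the module computes optimal and suboptimal coupling pathways
(simple paths within 1.5× of the shortest weighted path), divisive
Girvan–Newman communities cut at maximal modularity, and the per-node
information flow of one unit of current injected at a source and drained at
a sink (current-flow betweenness via the reduced network Laplacian).

All tie-breaks are lexicographic in node order, so outputs are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import Selection, Trajectory
from .metrics import kabsch_superpose

__all__ = [
    "PathSet", "FlowProfile", "covariance_matrix", "build_graph",
    "optimal_path", "suboptimal_paths", "detect_communities",
    "node_entropy", "entropy_from_samples", "mutual_information",
    "mutual_information_from_samples", "information_flow",
    "flow_profile_report", "fluctuation_amplitudes",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #


@dataclass
class PathSet:
    """Optimal path plus all suboptimal paths within the length cutoff."""

    source: Hashable
    sink: Hashable
    optimal_path: list
    optimal_length: float
    suboptimal_paths: list[list] = field(default_factory=list)
    suboptimal_lengths: list[float] = field(default_factory=list)
    cutoff_ratio: float = 0.5
    truncated: bool = False

    def all_paths(self) -> list[list]:
        return [self.optimal_path] + self.suboptimal_paths

    def to_frame(self) -> pd.DataFrame:
        recs = [{"rank": 0, "length": self.optimal_length,
                 "path": "-".join(map(str, self.optimal_path))}]
        for r, (p, L) in enumerate(zip(self.suboptimal_paths,
                                       self.suboptimal_lengths), start=1):
            recs.append({"rank": r, "length": L,
                         "path": "-".join(map(str, p))})
        return pd.DataFrame(recs)


@dataclass
class FlowProfile:
    """Per-node information flow for one source/sink pair."""

    source: Hashable
    sink: Hashable
    node_flow: dict
    potentials: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.node_flow),
            "flow": [self.node_flow[n] for n in self.node_flow],
            "potential": [self.potentials[n] for n in self.node_flow],
        })


# --------------------------------------------------------------------------- #
# covariance and graph construction
# --------------------------------------------------------------------------- #


def covariance_matrix(traj: Trajectory, selection: Selection,
                      superpose_reference: np.ndarray | None = None,
                      superpose: bool = True) -> np.ndarray:
    """Normalized covariance of node displacement vectors.

    Frames are rigid-body superposed onto the reference (default: the first
    frame's selected coordinates) before fluctuations are extracted, then

        C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩),

    so C is a correlation matrix with |C_ij| ≤ 1 and unit diagonal.  Pass
    ``superpose=False`` for trajectories whose rigid-body motion is already
    removed (the fit of a small node set otherwise injects spurious
    correlations of order 6/(3N)).
    """
    idx = selection.require_nonempty()
    if superpose:
        ref = (traj.coordinates[0, idx] if superpose_reference is None
               else np.asarray(superpose_reference, dtype=float))
        fitted = np.empty((traj.n_frames, len(idx), 3))
        for f in range(traj.n_frames):
            fitted[f], _, _ = kabsch_superpose(traj.coordinates[f, idx], ref)
    else:
        fitted = traj.coordinates[:, idx]
    mean = fitted.mean(axis=0)
    d = fitted - mean
    inner = np.einsum("fia,fja->ij", d, d) / traj.n_frames
    var = np.diag(inner).copy()
    if (var <= 0).any():
        bad = np.nonzero(var <= 0)[0]
        raise ValueError(f"zero-variance nodes at selection positions {bad}")
    return inner / np.sqrt(np.outer(var, var))


def build_graph(contact_map: pd.DataFrame | np.ndarray, C: np.ndarray,
                labels: Sequence[Hashable] | None = None) -> nx.Graph:
    """Contact graph weighted by w = −log|C|.

    ``contact_map`` is the boolean residue contact matrix (from the 5 Å/75%
    rule); edges with C = 0 are dropped (infinite weight), and |C| > 1 is an
    error signalling unnormalized input.
    """
    if isinstance(contact_map, pd.DataFrame):
        labels = list(contact_map.index) if labels is None else list(labels)
        contacts = contact_map.to_numpy(dtype=bool)
    else:
        contacts = np.asarray(contact_map, dtype=bool)
        labels = list(range(contacts.shape[0])) if labels is None else list(labels)
    C = np.asarray(C, dtype=float)
    if contacts.shape != C.shape:
        raise ValueError("contact map and covariance differ in shape")
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts[i, j]:
                continue
            c = C[i, j]
            if abs(c) > 1.0 + 1e-9:
                raise ValueError(
                    f"|C|={abs(c):.3f} > 1 on edge ({labels[i]}, {labels[j]}); "
                    "pass a normalized covariance")
            if c == 0.0:
                continue
            g.add_edge(labels[i], labels[j], C=float(c),
                       weight=float(-np.log(min(abs(c), 1.0))),
                       strength=float(abs(c)))
    return g


# --------------------------------------------------------------------------- #
# pathways
# --------------------------------------------------------------------------- #


def _path_length(graph: nx.Graph, path: Sequence) -> float:
    return float(sum(graph[u][v]["weight"] for u, v in zip(path, path[1:])))


def optimal_path(graph: nx.Graph, source: Hashable, sink: Hashable
                 ) -> tuple[list, float]:
    """Minimum-total-weight path; lexicographically smallest among ties."""
    try:
        length = nx.shortest_path_length(graph, source, sink, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise ValueError(f"no path between {source} and {sink}") from exc
    best = min(nx.all_shortest_paths(graph, source, sink, weight="weight"),
               key=lambda p: [str(n) for n in p])
    return best, float(length)


def suboptimal_paths(graph: nx.Graph, source: Hashable, sink: Hashable,
                     cutoff_ratio: float = 0.5,
                     max_paths: int = 1000) -> PathSet:
    """All simple paths within (1 + cutoff_ratio)× of the optimal length.

    Paths are enumerated in nondecreasing length order (Yen's k-shortest
    simple paths) and capped at ``max_paths`` with a truncation flag.
    """
    opt, opt_len = optimal_path(graph, source, sink)
    bound = (1.0 + cutoff_ratio) * opt_len
    subs: list[tuple[float, list]] = []
    truncated = False
    gen = nx.shortest_simple_paths(graph, source, sink, weight="weight")
    for k, p in enumerate(gen):
        L = _path_length(graph, p)
        if L > bound + 1e-12:
            break
        if list(p) != opt:
            subs.append((L, list(p)))
        if k + 1 >= max_paths:
            truncated = True
            break
    subs.sort(key=lambda t: (t[0], [str(n) for n in t[1]]))
    return PathSet(source, sink, opt, opt_len,
                   [p for _, p in subs], [L for L, _ in subs],
                   cutoff_ratio=cutoff_ratio, truncated=truncated)


# --------------------------------------------------------------------------- #
# communities
# --------------------------------------------------------------------------- #


def detect_communities(graph: nx.Graph, strength_attr: str = "strength"
                       ) -> tuple[list[set], float]:
    """Divisive Girvan–Newman communities cut at maximal modularity.

    Edges are removed in order of highest w-weighted betweenness; candidate
    partitions (including the initial connected components) are scored by
    modularity with |C| edge strength as affinity, and the best is returned.
    Ties keep the earliest (coarsest) partition.  Components are never merged.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    base = [set(c) for c in nx.connected_components(graph)]
    candidates = [base]
    if graph.number_of_edges() > 0:
        def most_valuable(g):
            bet = nx.edge_betweenness_centrality(g, weight="weight")
            return min(bet, key=lambda e: (-bet[e], [str(n) for n in e]))

        gn = nx.community.girvan_newman(graph, most_valuable_edge=most_valuable)
        candidates.extend([set(c) for c in part] for part in gn)

    def score(part):
        try:
            return nx.community.modularity(graph, part, weight=strength_attr)
        except ZeroDivisionError:
            return -1.0

    best, best_q = candidates[0], score(candidates[0])
    for part in candidates[1:]:
        q = score(part)
        if q > best_q + 1e-12:
            best, best_q = part, q
    return sorted(best, key=lambda s: sorted(str(n) for n in s)), best_q


# --------------------------------------------------------------------------- #
# entropy, mutual information
# --------------------------------------------------------------------------- #


def _fit_gmm(x: np.ndarray, max_components: int = 5, seed: int = 0):
    from sklearn.mixture import GaussianMixture

    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, n_init=10, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return best


def entropy_from_samples(x: np.ndarray, max_components: int = 5,
                         seed: int = 0) -> float:
    """Differential entropy H = ⟨−ln ρ̂(x)⟩ with a BIC-selected 1-D GMM."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if len(x) < 100:
        raise ValueError("entropy estimation needs >=100 samples")
    if x.std() < 1e-10:
        raise ValueError("degenerate (zero-variance) samples")
    gm = _fit_gmm(x, max_components, seed)
    return float(-gm.score_samples(x).mean())


def fluctuation_amplitudes(traj: Trajectory, selection: Selection,
                           superpose: bool = True) -> np.ndarray:
    """Per-frame scalar distance of each node to its mean position.

    Returns an (n_frames, n_nodes) array; this is the 1-D fluctuation
    coordinate whose density enters the entropy estimate.
    """
    idx = selection.require_nonempty()
    coords = traj.coordinates[:, idx]
    if superpose:
        ref = coords[0]
        coords = np.stack([kabsch_superpose(c, ref)[0] for c in coords])
    mean = coords.mean(axis=0)
    return np.linalg.norm(coords - mean, axis=2)


def node_entropy(traj: Trajectory, selection: Selection, node: int,
                 max_components: int = 5, seed: int = 0) -> float:
    """Entropy of one node's fluctuation-amplitude distribution (nats)."""
    x = fluctuation_amplitudes(traj, selection)[:, node]
    return entropy_from_samples(x, max_components, seed)


def mutual_information_from_samples(x_i: np.ndarray, x_j: np.ndarray,
                                    max_components: int = 5,
                                    seed: int = 0) -> float:
    """M_ij = H_i + H_j − H_ij with GMM density estimates (nats, clipped ≥0).

    Identical samples are the degenerate-joint special case: M = H_i.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("sample arrays must have equal length")
    h_i = entropy_from_samples(x_i, max_components, seed)
    if np.allclose(x_i, x_j):
        return h_i
    h_j = entropy_from_samples(x_j, max_components, seed)
    xy = np.c_[x_i, x_j]
    if len(xy) < 100:
        raise ValueError("mutual information needs >=100 samples")
    gm = _fit_gmm(xy, max_components, seed)
    h_ij = float(-gm.score_samples(xy).mean())
    m = h_i + h_j - h_ij
    if m < 0:
        if m < -0.2:
            warnings.warn(f"strongly negative MI estimate ({m:.3f}) clipped to 0")
        m = 0.0
    return m


def mutual_information(traj: Trajectory, selection: Selection, node_i: int,
                       node_j: int, max_components: int = 5,
                       seed: int = 0) -> float:
    """Pairwise mutual information between two nodes' fluctuation amplitudes."""
    amp = fluctuation_amplitudes(traj, selection)
    return mutual_information_from_samples(amp[:, node_i], amp[:, node_j],
                                           max_components, seed)


# --------------------------------------------------------------------------- #
# information flow
# --------------------------------------------------------------------------- #


def information_flow(graph: nx.Graph, source: Hashable, sink: Hashable,
                     conductance_attr: str = "A") -> FlowProfile:
    """Unit-current flow through every node between a source and a sink.

    Solves the reduced network Laplacian L = D − A (sink row/column removed,
    P_sink = 0) for node potentials with a unit supply at the source, then
    assigns each interior node f_i = ½ Σ_j |P_i − P_j| A_ij.  The source and
    sink carry the full unit of current by construction and are reported as
    f = 1.  Equals current-flow (random-walk) betweenness of the pair.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    for n in (source, sink):
        if n not in graph:
            raise ValueError(f"node {n} not in graph")
    component = nx.node_connected_component(graph, source)
    if sink not in component:
        raise ValueError(
            "singular reduced Laplacian: source and sink are not connected "
            "through the conductance graph")
    if component != set(graph.nodes):
        # nodes unreachable from the supply carry no current
        sub = information_flow(graph.subgraph(component), source, sink,
                               conductance_attr)
        for n in graph.nodes:
            if n not in component:
                sub.node_flow[n] = 0.0
                sub.potentials[n] = 0.0
        return sub
    nodes = sorted(graph.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, data in graph.edges(data=True):
        a = data.get(conductance_attr)
        if a is None:
            raise ValueError(f"edge ({u}, {v}) lacks conductance {conductance_attr!r}")
        if a < 0:
            raise ValueError("conductances must be non-negative")
        A[index[u], index[v]] = A[index[v], index[u]] = a
    L = np.diag(A.sum(axis=1)) - A
    keep = [i for i in range(len(nodes)) if nodes[i] != sink]
    b = np.zeros(len(keep))
    b[[nodes[i] for i in keep].index(source)] = 1.0
    L_red = L[np.ix_(keep, keep)]
    try:
        P_red = np.linalg.solve(L_red, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular reduced Laplacian: source and sink are not connected "
            "through the conductance graph") from exc
    if not np.isfinite(P_red).all():
        raise ValueError("non-finite potentials (disconnected graph?)")
    P = np.zeros(len(nodes))
    P[keep] = P_red
    flow = {}
    for n in nodes:
        i = index[n]
        if n == source or n == sink:
            flow[n] = 1.0
            continue
        flow[n] = 0.5 * float(np.abs(P[i] - P) @ A[i])
    potentials = {n: float(P[index[n]]) for n in nodes}
    return FlowProfile(source, sink, flow, potentials)


def flow_profile_report(profile: FlowProfile,
                        highlight_threshold: float = 0.02) -> pd.DataFrame:
    """Nodes ranked by flow (descending) with a strict-> highlight flag."""
    df = profile.to_frame().sort_values(
        ["flow", "node"], ascending=[False, True],
        key=lambda s: s if s.name == "flow" else s.astype(str))
    df["highlight"] = df["flow"] > highlight_threshold
    return df.reset_index(drop=True)
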