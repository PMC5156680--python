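"""Protein structure networks from conformational ensembles.

Nodes are the non-glycine residues; an edge joins two residues whose
side-chain centers of mass fall within a distance cutoff (0.5 nm by
default) in a frame, and an edge enters the final network only when the
contact is present in at least a critical fraction of frames
(p_crit = 0.20 by default).  The edge weight is that occurrence fraction.

On top of the persistence-filtered graph the module reports hubs (high
degree nodes), connected components with zero-degree "orphans", all
minimal-hop communication paths between residue pairs, cutoff sensitivity
diagnostics, and jack-knife convergence of the network under leave-10%-out
frame resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml
from scipy.spatial.distance import pdist, squareform

from .ensemble import ConformationalEnsemble, ResidueId, sidechain_com

__all__ = [
    "PsnConfig",
    "Psn",
    "CommunicationPath",
    "PathReport",
    "ConnectedComponentReport",
    "CutoffReport",
    "JackknifeReport",
    "frame_contacts",
    "build_psn",
    "find_hubs",
    "connected_components",
    "cutoff_diagnostic",
    "shortest_paths",
    "jackknife_psn",
    "to_edge_table",
    "write_graphml",
]


@dataclass
class PsnConfig:
    """Parameters of network construction.

    distance_cutoff : side-chain COM contact cutoff in nm (0.5 or 0.55
        are the values worth comparing; above 0.55 the network tends to
        collapse into one giant component).
    p_crit : minimum occurrence fraction for an edge to be retained.
    hub_min_degree : degree threshold for hubs; ``hub_strict`` switches the
        comparison from ``>=`` to ``>`` (both conventions are in use).
    boundary_inclusive : whether d == cutoff counts as a contact.
    weight_scale : factor applied to occurrence when reporting path edge
        weights (100 -> percent scale).
    collapse_fraction : a cutoff is flagged "collapsed" when the largest
        component holds more than this fraction of the nodes.
    """

    distance_cutoff: float = 0.5
    p_crit: float = 0.20
    hub_min_degree: int = 3
    hub_strict: bool = False
    boundary_inclusive: bool = True
    include_hydrogens: bool = False
    weight_scale: float = 100.0
    collapse_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.distance_cutoff > 0:
            raise ValueError("distance_cutoff must be > 0")
        if not 0.0 <= self.p_crit <= 1.0:
            raise ValueError("p_crit must lie in [0, 1]")
        if self.hub_min_degree < 1:
            raise ValueError("hub_min_degree must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PsnConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _node_key(r: ResidueId) -> tuple[str, int]:
    return (r.chain, r.resnum)


@dataclass
class Psn:
    """A persistence-filtered residue graph.

    ``graph`` is an undirected networkx graph whose nodes are
    :class:`ResidueId` and whose edges carry an ``occurrence`` attribute in
    (0, 1].
    """

    graph: nx.Graph
    config: PsnConfig
    n_frames: int

    @property
    def nodes(self) -> list[ResidueId]:
        return sorted(self.graph.nodes, key=_node_key)

    @property
    def edges(self) -> list[tuple[ResidueId, ResidueId, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v), key=_node_key)
            out.append((a, b, d["occurrence"]))
        return sorted(out, key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    def occurrence(self, a: ResidueId, b: ResidueId) -> float:
        return self.graph.edges[a, b]["occurrence"]


@dataclass
class CommunicationPath:
    """One minimal-hop path with its occurrence-derived weights."""

    nodes: list[ResidueId]
    edge_weights: list[float]  # occurrence on the configured (percent) scale
    sum_weight: float = field(init=False)
    avg_weight: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.edge_weights) != len(self.nodes) - 1:
            raise ValueError("edge count must equal node count - 1")
        self.sum_weight = float(sum(self.edge_weights))
        self.avg_weight = self.sum_weight / len(self.edge_weights)

    @property
    def n_intermediates(self) -> int:
        return len(self.nodes) - 2


@dataclass
class PathReport:
    source: ResidueId
    target: ResidueId
    connected: bool
    paths: list[CommunicationPath]


@dataclass
class ConnectedComponentReport:
    """Components (size >= 2) sorted by descending size, plus orphan nodes."""

    components: list[list[ResidueId]]
    orphans: list[ResidueId]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def top_sizes(self, n: int = 5) -> list[int]:
        return self.sizes[:n]


@dataclass
class CutoffReport:
    cutoff: float
    n_edges: int
    top_component_sizes: list[int]
    hub_degree_histogram: dict[int, int]
    collapsed: bool


@dataclass
class JackknifeBlock:
    block_index: int
    dropped_frames: tuple[int, int]  # half-open [start, stop)
    edge_jaccard: float
    hub_jaccard: float
    top_component_sizes: list[int]


@dataclass
class JackknifeReport:
    full_psn: Psn
    blocks: list[JackknifeBlock]

    @property
    def mean_edge_jaccard(self) -> float:
        return float(np.mean([b.edge_jaccard for b in self.blocks]))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def frame_contacts(
    coms: np.ndarray, cutoff: float, boundary_inclusive: bool = True
) -> set[tuple[int, int]]:
    """Contacting index pairs for one frame of side-chain COMs (n, 3)."""
    coms = np.asarray(coms, dtype=float)
    n = coms.shape[0]
    if n < 2:
        return set()
    d = squareform(pdist(coms))
    mask = d <= cutoff if boundary_inclusive else d < cutoff
    ii, jj = np.where(np.triu(mask, k=1))
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


def _com_stack(ensemble: ConformationalEnsemble, config: PsnConfig):
    """(residues, per-frame COM array of shape (n_frames, n_res, 3)), glycine dropped."""
    residues = [r for r in ensemble.residues if r.resname != "GLY"]
    coms = np.stack(
        [sidechain_com(ensemble, r, include_hydrogens=config.include_hydrogens)
         for r in residues],
        axis=1,
    )
    return residues, coms


def build_psn(ensemble: ConformationalEnsemble, config: PsnConfig | None = None) -> Psn:
    """Build the persistence-filtered PSN of an ensemble.

    Edge occurrence is (#frames with the contact) / (#frames); edges with
    occurrence below ``p_crit`` are dropped.
    """
    config = config or PsnConfig()
    if ensemble.n_frames < 1:
        raise ValueError("ensemble must contain at least one frame")
    residues, coms = _com_stack(ensemble, config)
    return _psn_from_coms(residues, coms, config)


def _psn_from_coms(residues: list[ResidueId], coms: np.ndarray, config: PsnConfig) -> Psn:
    n_frames = coms.shape[0]
    counts: dict[tuple[int, int], int] = {}
    for f in range(n_frames):
        for pair in frame_contacts(coms[f], config.distance_cutoff, config.boundary_inclusive):
            counts[pair] = counts.get(pair, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(residues)
    for (i, j), c in counts.items():
        occ = c / n_frames
        if occ >= config.p_crit and occ > 0:
            g.add_edge(residues[i], residues[j], occurrence=occ)
    return Psn(graph=g, config=config, n_frames=n_frames)


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def find_hubs(
    psn: Psn, min_degree: int | None = None, strict: bool | None = None
) -> list[tuple[ResidueId, int]]:
    """Hub residues with their degrees, sorted by descending degree then residue order.

    Default convention: degree >= min_degree.  ``strict=True`` requires the
    degree to exceed the threshold instead.
    """
    min_degree = psn.config.hub_min_degree if min_degree is None else min_degree
    strict = psn.config.hub_strict if strict is None else strict
    hubs = []
    for node in psn.graph.nodes:
        deg = psn.graph.degree[node]
        if (deg > min_degree) if strict else (deg >= min_degree):
            hubs.append((node, deg))
    return sorted(hubs, key=lambda h: (-h[1], _node_key(h[0])))


def connected_components(psn: Psn) -> ConnectedComponentReport:
    """Connected components of the PSN; zero-degree nodes are reported as orphans."""
    orphans = sorted((n for n in psn.graph.nodes if psn.graph.degree[n] == 0), key=_node_key)
    comps = [sorted(c, key=_node_key) for c in nx.connected_components(psn.graph) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), _node_key(c[0])))
    return ConnectedComponentReport(components=comps, orphans=orphans)


def cutoff_diagnostic(
    ensemble: ConformationalEnsemble,
    cutoffs: Sequence[float],
    config: PsnConfig | None = None,
) -> list[CutoffReport]:
    """Rebuild the PSN at each cutoff and summarize component/hub structure.

    A cutoff is flagged "collapsed" when the largest connected component
    holds more than ``config.collapse_fraction`` of the nodes — the
    signature of a cutoff too generous to resolve network structure.
    """
    if len(cutoffs) == 0:
        raise ValueError("need at least one cutoff")
    config = config or PsnConfig()
    residues, coms = _com_stack(ensemble, config)
    reports = []
    for cutoff in cutoffs:
        psn = _psn_from_coms(residues, coms, replace(config, distance_cutoff=cutoff))
        comp = connected_components(psn)
        hist: dict[int, int] = {}
        for node, deg in find_hubs(psn):
            hist[deg] = hist.get(deg, 0) + 1
        largest = comp.sizes[0] if comp.sizes else 0
        reports.append(
            CutoffReport(
                cutoff=float(cutoff),
                n_edges=psn.graph.number_of_edges(),
                top_component_sizes=comp.top_sizes(5),
                hub_degree_histogram=hist,
                collapsed=largest > config.collapse_fraction * psn.graph.number_of_nodes(),
            )
        )
    return reports


def shortest_paths(psn: Psn, source: ResidueId, target: ResidueId) -> PathReport:
    """All minimal-hop communication paths between two residues.

    Hop count is the path length (directly connected nodes are at distance
    one); every path of minimal length is returned, ordered
    lexicographically by node sequence, each annotated with the sum and
    average of its edge occurrence weights on the configured scale.
    A disconnected pair yields ``connected=False`` with no paths.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in psn.graph:
            raise KeyError(f"residue {node} not in the network")
    if not nx.has_path(psn.graph, source, target):
        return PathReport(source, target, connected=False, paths=[])
    raw = sorted(
        nx.all_shortest_paths(psn.graph, source, target),
        key=lambda p: [_node_key(n) for n in p],
    )
    scale = psn.config.weight_scale
    paths = [
        CommunicationPath(
            nodes=list(p),
            edge_weights=[psn.occurrence(a, b) * scale for a, b in zip(p, p[1:])],
        )
        for p in raw
    ]
    return PathReport(source, target, connected=True, paths=paths)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def jackknife_psn(
    ensemble: ConformationalEnsemble,
    config: PsnConfig | None = None,
    drop_fraction: float = 0.10,
) -> JackknifeReport:
    """Leave-one-block-out convergence check of the PSN.

    The frame axis is split into ``round(1/drop_fraction)`` contiguous
    blocks at regular intervals; each block in turn is discarded, the PSN is
    rebuilt, and its edge set, hub set and top component sizes are compared
    with the full-ensemble network.  ``drop_fraction=0`` degenerates to a
    single self-comparison (similarity 1).
    """
    config = config or PsnConfig()
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if ensemble.n_frames < 10:
        raise ValueError("jack-knife needs at least 10 frames")
    residues, coms = _com_stack(ensemble, config)
    full = _psn_from_coms(residues, coms, config)
    full_edges = {frozenset((u, v)) for u, v in full.graph.edges}
    full_hubs = {h for h, _ in find_hubs(full)}

    n = ensemble.n_frames
    blocks: list[JackknifeBlock] = []
    if drop_fraction == 0.0:
        block_bounds = [(0, 0)]
    else:
        n_blocks = max(1, round(1.0 / drop_fraction))
        block_bounds = [
            (n * b // n_blocks, n * (b + 1) // n_blocks) for b in range(n_blocks)
        ]
    for b, (start, stop) in enumerate(block_bounds):
        keep = [f for f in range(n) if not start <= f < stop]
        sub = _psn_from_coms(residues, coms[keep], config)
        sub_edges = {frozenset((u, v)) for u, v in sub.graph.edges}
        sub_hubs = {h for h, _ in find_hubs(sub)}
        blocks.append(
            JackknifeBlock(
                block_index=b,
                dropped_frames=(start, stop),
                edge_jaccard=_jaccard(full_edges, sub_edges),
                hub_jaccard=_jaccard(full_hubs, sub_hubs),
                top_component_sizes=connected_components(sub).top_sizes(5),
            )
        )
    return JackknifeReport(full_psn=full, blocks=blocks)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def to_edge_table(psn: Psn):
    """Edge list as a DataFrame (chain/resnum/resname per endpoint + occurrence)."""
    import pandas as pd

    rows = [
        (a.chain, a.resnum, a.resname, b.chain, b.resnum, b.resname, occ)
        for a, b, occ in psn.edges
    ]
    return pd.DataFrame(
        rows,
        columns=["chain_a", "resnum_a", "resname_a",
                 "chain_b", "resnum_b", "resname_b", "occurrence"],
    )


def write_graphml(psn: Psn, path: str | Path) -> None:
    """GraphML export with degree / hub flag / component id node attributes."""
    comp_report = connected_components(psn)
    comp_of: dict[ResidueId, int] = {}
    for ci, comp in enumerate(comp_report.components):
        for node in comp:
            comp_of[node] = ci
    hubs = {h for h, _ in find_hubs(psn)}
    g = nx.Graph()
    for node in psn.nodes:
        g.add_node(
            str(node),
            chain=node.chain,
            resnum=node.resnum,
            resname=node.resname,
            degree=psn.graph.degree[node],
            is_hub=node in hubs,
            component=comp_of.get(node, -1),
        )
    for a, b, occ in psn.edges:
        g.add_edge(str(a), str(b), occurrence=occ)
    nx.write_graphml(g, str(path))
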