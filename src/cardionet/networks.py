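"""Bipartite target–pathway and compound–pathway networks.

A target is linked to a pathway if it appears among the pathway's
members; a compound is linked to every pathway containing at least one
of its direct targets.  The degree distribution f(x) is the fraction of
nodes (on one side) with degree x; biological networks typically show
heavy-tailed, approximately power-law f(x) ∝ x^(−γ), which is assessed
by a log-log least-squares fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import linregress

from .enrichment import EnrichmentResult
from .types import (
    CardionetError,
    Compound,
    PathwaySet,
    TargetAnnotation,
)


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


@dataclass
class BipartiteNetwork:
    """Typed bipartite graph with left nodes (targets or compounds) and
    right nodes (pathways); node attributes carry degree, node kind and,
    for pathway nodes, the enrichment p-value when available."""

    left_nodes: set[str] = field(default_factory=set)
    right_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    node_attrs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [e for e in self.edges if e[0] not in self.left_nodes or e[1] not in self.right_nodes]
        if bad:
            raise CardionetError(f"edges outside the node sets: {bad[:3]}")

    def degree(self, node: str) -> int:
        if node in self.left_nodes:
            return sum(1 for l, _ in self.edges if l == node)
        return sum(1 for _, r in self.edges if r == node)

    def degrees(self, side: Side) -> dict[str, int]:
        nodes = self.left_nodes if side is Side.LEFT else self.right_nodes
        out = dict.fromkeys(nodes, 0)
        idx = 0 if side is Side.LEFT else 1
        for e in self.edges:
            out[e[idx]] += 1
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        ldeg, rdeg = self.degrees(Side.LEFT), self.degrees(Side.RIGHT)
        for n in sorted(self.left_nodes):
            g.add_node(n, bipartite=0, degree=ldeg[n], **self._clean_attrs(n))
        for n in sorted(self.right_nodes):
            g.add_node(n, bipartite=1, degree=rdeg[n], **self._clean_attrs(n))
        g.add_edges_from(sorted(self.edges))
        return g

    def _clean_attrs(self, node: str) -> dict:
        return {k: v for k, v in self.node_attrs.get(node, {}).items() if v is not None}

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BipartiteNetwork":
        left = {n for n, d in g.nodes(data=True) if d.get("bipartite", 0) == 0}
        right = set(g.nodes) - left
        edges = set()
        for u, v in g.edges:
            edges.add((u, v) if u in left else (v, u))
        attrs = {
            n: {k: v for k, v in d.items() if k not in {"bipartite", "degree"}}
            for n, d in g.nodes(data=True)
        }
        return cls(left, right, edges, attrs)


@dataclass
class DegreeDistribution:
    points: list[tuple[int, float]]  # (degree x, frequency f(x))
    n_nodes: int
    fitted_exponent: float | None = None
    fit_r2: float | None = None


def build_target_pathway_network(
    target_set: set[str],
    pathways: Sequence[PathwaySet],
    enrichment: Sequence[EnrichmentResult] = (),
    significant_only: bool = False,
) -> BipartiteNetwork:
    """Edge (t, P) iff target t belongs to pathway P.

    All targets of the set are retained as nodes even when isolated;
    pathway nodes appear only if they have at least one edge (or, with
    *significant_only*, only if enriched)."""
    pmap = {r.pathway_id: r for r in enrichment}
    edges = set()
    right = set()
    attrs: dict[str, dict] = {t: {"node_kind": "target"} for t in target_set}
    for p in pathways:
        if significant_only and not (p.pathway_id in pmap and pmap[p.pathway_id].significant):
            continue
        hits = p.members & target_set
        if not hits:
            continue
        right.add(p.pathway_id)
        r = pmap.get(p.pathway_id)
        attrs[p.pathway_id] = {
            "node_kind": "pathway",
            "category": p.category.value,
            "p_value": r.p_value if r else None,
            "significant": bool(r.significant) if r else None,
        }
        edges |= {(t, p.pathway_id) for t in hits}
    return BipartiteNetwork(set(target_set), right, edges, attrs)


def build_compound_pathway_network(
    compounds: Iterable[Compound],
    annotations: Mapping[str, TargetAnnotation],
    pathways: Sequence[PathwaySet],
    per_compound_enrichment: Mapping[str, Sequence[EnrichmentResult]] | None = None,
) -> BipartiteNetwork:
    """Edge (c, P) iff some direct target of compound c lies in pathway P.

    Only direct targets are used (for herbal ingredients the indirect
    links are deliberately excluded from the comparative analysis)."""
    per_compound_enrichment = per_compound_enrichment or {}
    left, right, edges = set(), set(), set()
    attrs: dict[str, dict] = {}
    for c in compounds:
        left.add(c.compound_id)
        attrs[c.compound_id] = {
            "node_kind": "compound",
            "compound_class": c.compound_class.value,
        }
        targets = c.direct_targets
        for p in pathways:
            if targets & p.members:
                edges.add((c.compound_id, p.pathway_id))
                right.add(p.pathway_id)
                if p.pathway_id not in attrs:
                    attrs[p.pathway_id] = {
                        "node_kind": "pathway",
                        "category": p.category.value,
                    }
    return BipartiteNetwork(left, right, edges, attrs)


def degree_distribution(network: BipartiteNetwork, side: Side | str = Side.LEFT) -> DegreeDistribution:
    """Empirical degree distribution on one side (or both pooled) as
    fractions of that side's nodes; zero-degree nodes appear as an x=0
    point (excluded later from power-law fitting)."""
    side = Side(side)
    if side is Side.BOTH:
        degs = list(network.degrees(Side.LEFT).values()) + list(
            network.degrees(Side.RIGHT).values()
        )
    else:
        degs = list(network.degrees(side).values())
    if not degs:
        raise CardionetError(f"no nodes on side {side.value}")
    n = len(degs)
    vals, counts = np.unique(np.asarray(degs), return_counts=True)
    points = [(int(x), c / n) for x, c in zip(vals, counts)]
    return DegreeDistribution(points, n)


def fit_power_law(
    distribution: DegreeDistribution,
    x_min: int = 1,
    binning: str = "none",
    n_bins: int = 12,
) -> tuple[float, float]:
    """Least-squares fit of log f(x) against log x for x >= x_min.

    Returns ``(exponent, r2)`` with the exponent reported positive
    (f(x) ∝ x^(−exponent)).  ``binning="none"`` fits the per-degree
    frequencies directly and is exact on noiseless power-law input;
    ``binning="log"`` aggregates frequencies into logarithmically spaced
    degree bins (normalized per unit degree) before fitting, the
    appropriate estimator for finite samples whose sparse tail otherwise
    flattens the per-degree fit.
    """
    pts = [(x, f) for x, f in distribution.points if x >= x_min and f > 0]
    if len(pts) < 3:
        raise CardionetError("need >=3 distinct degrees >= x_min to fit")
    if binning == "log":
        xs = np.array([x for x, _ in pts], dtype=float)
        fs = np.array([f for _, f in pts])
        edges = np.unique(
            np.round(np.logspace(np.log10(x_min), np.log10(xs.max() + 1), n_bins + 1))
        ).astype(int)
        log_x, log_f = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (xs >= lo) & (xs < hi)
            if not m.any():
                continue
            dens = fs[m].sum() / (hi - lo)
            log_x.append(np.log(np.sqrt(lo * max(hi - 1, lo))))
            log_f.append(np.log(dens))
        if len(log_x) < 3:
            raise CardionetError("too few populated log bins to fit")
        fit = linregress(log_x, log_f)
    elif binning == "none":
        fit = linregress(
            np.log([x for x, _ in pts]), np.log([f for _, f in pts])
        )
    else:
        raise CardionetError(f"unknown binning mode {binning!r}")
    return -fit.slope, fit.rvalue**2


def write_network(network: BipartiteNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write as GraphML (with node attributes) or a 2-column TSV edge list."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif fmt == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("left_id\tright_id\n")
            for l, r in sorted(network.edges):
                fh.write(f"{l}\t{r}\n")
    else:
        raise CardionetError(f"unknown format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml") -> BipartiteNetwork:
    path = Path(path)
    if fmt == "graphml":
        return BipartiteNetwork.from_networkx(nx.read_graphml(path))
    if fmt == "edgelist":
        left, right, edges = set(), set(), set()
        with path.open(encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                l, r = line.rstrip("\n").split("\t")
                left.add(l)
                right.add(r)
                edges.add((l, r))
        return BipartiteNetwork(left, right, edges)
    raise CardionetError(f"unknown format {fmt!r}")
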