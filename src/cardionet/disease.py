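"""Curated cardiovascular-disease subnetworks and class coverage.

The analysis builds small signed signalling networks around two CVD
mechanisms — apoptosis and vascular endothelial cell contraction — plus
a merged whole-CVD network, then asks which nodes the two compound
classes reach and where those nodes sit (upstream/receptor-proximal vs
downstream/effector-proximal; compartment: blood, membrane, cytoplasm,
nucleus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .types import (
    CardionetError,
    Compound,
    CompoundClass,
    Effect,
    Location,
    ParseError,
    Position,
    SchemaError,
    TargetAnnotation,
)

HERBAL = "herbal"
WESTERN = "western"


@dataclass(frozen=True)
class NodeInfo:
    compartment: Location
    position: Position


@dataclass
class DiseaseSubnetwork:
    name: str
    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    edges: list[tuple[str, str, Effect]] = field(default_factory=list)
    regulators: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, t, _ in self.edges:
            for endpoint in (s, t):
                if endpoint not in self.nodes:
                    raise CardionetError(
                        f"{self.name}: edge endpoint {endpoint!r} not in node table"
                    )
        unknown = set(self.regulators) - set(self.nodes)
        if unknown:
            raise CardionetError(f"{self.name}: regulators for unknown nodes {unknown}")


@dataclass(frozen=True)
class CoverageSummary:
    """Per-class counts of regulated nodes, overall and by position /
    compartment; ``n_common_targets`` counts nodes hit by both classes."""

    subnetwork_name: str
    n_herbal_targets: int
    n_western_targets: int
    n_common_targets: int
    per_position: dict[Position, tuple[int, int]]  # (herbal, western)
    per_compartment: dict[Location, tuple[int, int]]


def assemble_subnetwork(
    edge_table: str | Path, node_table: str | Path, name: str
) -> DiseaseSubnetwork:
    """Load a subnetwork from its edge/node TSV pair.

    The node table must list every id referenced by an edge; a dangling
    endpoint is an error naming the node.
    """
    nodes: dict[str, NodeInfo] = {}
    with Path(node_table).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        required = {"node_id", "compartment", "position"}
        if not required <= set(reader.fieldnames or []):
            raise SchemaError(f"{node_table}: need columns {sorted(required)}")
        for i, row in enumerate(reader, 2):
            try:
                nodes[row["node_id"].strip()] = NodeInfo(
                    Location(row["compartment"].strip()),
                    Position(row["position"].strip() or "unassigned"),
                )
            except ValueError as e:
                raise ParseError(str(e), i) from None
    edges: list[tuple[str, str, Effect]] = []
    with Path(edge_table).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        required = {"source_id", "target_id", "effect"}
        if not required <= set(reader.fieldnames or []):
            raise SchemaError(f"{edge_table}: need columns {sorted(required)}")
        for i, row in enumerate(reader, 2):
            try:
                effect = Effect(row["effect"].strip())
            except ValueError:
                raise ParseError(f"unknown effect {row['effect']!r}", i) from None
            edges.append((row["source_id"].strip(), row["target_id"].strip(), effect))
    return DiseaseSubnetwork(name, nodes, edges)


def write_subnetwork(
    sub: DiseaseSubnetwork, edge_table: str | Path, node_table: str | Path
) -> None:
    with Path(node_table).open("w", encoding="utf-8") as fh:
        fh.write("node_id\tcompartment\tposition\n")
        for nid in sorted(sub.nodes):
            info = sub.nodes[nid]
            fh.write(f"{nid}\t{info.compartment.value}\t{info.position.value}\n")
    with Path(edge_table).open("w", encoding="utf-8") as fh:
        fh.write("source_id\ttarget_id\teffect\n")
        for s, t, e in sub.edges:
            fh.write(f"{s}\t{t}\t{e.value}\n")


def annotate_regulators(
    sub: DiseaseSubnetwork,
    compounds: Iterable[Compound],
    annotations: Mapping[str, TargetAnnotation] | None = None,
) -> DiseaseSubnetwork:
    """Return a copy in which every node carries the set of compound
    classes that directly target it (herbal ingredients contribute via
    direct links only).  Nodes hit by both classes are the "common"
    targets of the coverage summary."""
    regs: dict[str, set[str]] = {}
    for c in compounds:
        label = HERBAL if c.compound_class is CompoundClass.HERBAL_INGREDIENT else WESTERN
        for t in c.direct_targets:
            if t in sub.nodes:
                regs.setdefault(t, set()).add(label)
    return DiseaseSubnetwork(sub.name, dict(sub.nodes), list(sub.edges), regs)


def coverage_summary(sub: DiseaseSubnetwork) -> CoverageSummary:
    """Count regulated nodes per class, position and compartment."""
    herbal = {n for n, r in sub.regulators.items() if HERBAL in r}
    western = {n for n, r in sub.regulators.items() if WESTERN in r}
    per_position = {}
    for pos in Position:
        nodes = {n for n, info in sub.nodes.items() if info.position is pos}
        per_position[pos] = (len(herbal & nodes), len(western & nodes))
    per_compartment = {}
    for loc in Location:
        nodes = {n for n, info in sub.nodes.items() if info.compartment is loc}
        per_compartment[loc] = (len(herbal & nodes), len(western & nodes))
    return CoverageSummary(
        subnetwork_name=sub.name,
        n_herbal_targets=len(herbal),
        n_western_targets=len(western),
        n_common_targets=len(herbal & western),
        per_position=per_position,
        per_compartment=per_compartment,
    )


def position_preference(
    summary: CoverageSummary,
) -> tuple[float | None, float | None]:
    """(herbal downstream fraction, western upstream fraction) among the
    regulated nodes with an assigned cascade position; ``None`` when a
    class regulates no positioned node."""
    h_up, w_up = summary.per_position[Position.UPSTREAM]
    h_down, w_down = summary.per_position[Position.DOWNSTREAM]
    herbal_frac = h_down / (h_up + h_down) if (h_up + h_down) else None
    western_frac = w_up / (w_up + w_down) if (w_up + w_down) else None
    return herbal_frac, western_frac


def summary_as_dict(summary: CoverageSummary) -> dict:
    """JSON-friendly rendering of a coverage summary."""
    herbal_down, western_up = position_preference(summary)
    return {
        "subnetwork": summary.subnetwork_name,
        "n_herbal_targets": summary.n_herbal_targets,
        "n_western_targets": summary.n_western_targets,
        "n_common_targets": summary.n_common_targets,
        "per_position": {
            p.value: {"herbal": h, "western": w}
            for p, (h, w) in summary.per_position.items()
        },
        "per_compartment": {
            l.value: {"herbal": h, "western": w}
            for l, (h, w) in summary.per_compartment.items()
        },
        "herbal_downstream_fraction": herbal_down,
        "western_upstream_fraction": western_up,
    }
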