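"""Readers and writers for the normalized fixture formats.

Three plain-text carriers feed the pipeline:

* ``compounds.tsv`` — one compound→target link per row
  (``compound_id, name, compound_class, target_id, link_type``);
* ``annotations.tsv`` — one target per row, list-valued cells
  (diseases, domains, locations) joined with ``;``;
* ``pathways.gmt`` — standard GMT (set id, description, members...),
  with the basic/disease category read from a token in the description.

Lines starting with ``#`` are comments.  Parsing is order-independent:
shuffling data rows yields the same in-memory dataset.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .types import (
    Compound,
    CompoundClass,
    Dataset,
    LinkType,
    Location,
    ParseError,
    PathwayCategory,
    PathwaySet,
    ProteinFamily,
    SchemaError,
    TargetAnnotation,
    TTDStatus,
    ValidationError,
    ValidationReport,
)

LIST_SEP = ";"

COMPOUND_COLUMNS = ["compound_id", "name", "compound_class", "target_id", "link_type"]
ANNOTATION_COLUMNS = [
    "target_id",
    "name",
    "ttd_status",
    "diseases",
    "domain_ids",
    "family",
    "locations",
    "is_tf",
    "tf_gene_count",
]


def _rows(path: str | Path, required: list[str]):
    """Yield (line_number, row_dict) from a commented TSV, validating the
    header against *required* columns."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [
            (i + 1, line)
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        raise SchemaError(f"{path}: empty file (no header)")
    header_line_no, header_line = lines[0]
    header = next(csv.reader([header_line], delimiter="\t"))
    header = [h.strip() for h in header]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for line_no, line in lines[1:]:
        cells = next(csv.reader([line], delimiter="\t"))
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        yield line_no, {h: c.strip() for h, c in zip(header, cells)}


def _enum(cls, token: str, line: int, what: str):
    try:
        return cls(token)
    except ValueError:
        raise ParseError(f"unknown {what} {token!r}", line) from None


def _split_list(cell: str) -> list[str]:
    return [s.strip() for s in cell.split(LIST_SEP) if s.strip()]


def read_compound_table(path: str | Path) -> list[Compound]:
    """Read a compound link table into one :class:`Compound` per id.

    Links are aggregated across rows and deduplicated; conflicting
    name/class for one id is a validation error.
    """
    records: dict[str, dict] = {}
    for line_no, row in _rows(path, COMPOUND_COLUMNS):
        cid = row["compound_id"]
        if not cid:
            raise ParseError("empty compound_id", line_no)
        cclass = _enum(CompoundClass, row["compound_class"], line_no, "compound_class")
        link = (row["target_id"], _enum(LinkType, row["link_type"], line_no, "link_type"))
        rec = records.setdefault(
            cid, {"name": row["name"], "class": cclass, "links": set()}
        )
        if rec["name"] != row["name"] or rec["class"] is not cclass:
            raise ValidationError(
                f"compound {cid}: conflicting name/class across rows"
            )
        if link[0]:
            rec["links"].add(link)
    return [
        Compound(cid, rec["name"], rec["class"], sorted(rec["links"]))
        for cid, rec in sorted(records.items())
    ]


def write_compound_table(compounds: Iterable[Compound], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COMPOUND_COLUMNS)
        for c in sorted(compounds, key=lambda c: c.compound_id):
            for tid, lt in sorted(c.target_links):
                w.writerow([c.compound_id, c.name, c.compound_class.value, tid, lt.value])


def read_annotation_table(path: str | Path) -> dict[str, TargetAnnotation]:
    """Read per-target annotations keyed by target id.

    Unlisted optional fields default to absent/empty/false; a duplicate
    target id with conflicting fields is a validation error (an exact
    duplicate row is tolerated).
    """
    out: dict[str, TargetAnnotation] = {}
    for line_no, row in _rows(path, ["target_id"]):
        tid = row["target_id"]
        if not tid:
            raise ParseError("empty target_id", line_no)
        tf_cell = row.get("is_tf", "") or "0"
        if tf_cell not in {"0", "1"}:
            raise ParseError(f"malformed boolean is_tf={tf_cell!r}", line_no)
        status_cell = row.get("ttd_status", "") or TTDStatus.ABSENT.value
        family_cell = row.get("family", "") or ProteinFamily.OTHER.value
        try:
            count = int(row.get("tf_gene_count", "") or "0")
        except ValueError:
            raise ParseError(
                f"malformed tf_gene_count {row['tf_gene_count']!r}", line_no
            ) from None
        ann = TargetAnnotation(
            target_id=tid,
            name=row.get("name", ""),
            ttd_status=_enum(TTDStatus, status_cell, line_no, "ttd_status"),
            diseases=frozenset(_split_list(row.get("diseases", ""))),
            domain_ids=tuple(_split_list(row.get("domain_ids", ""))),
            family=_enum(ProteinFamily, family_cell, line_no, "family"),
            locations=frozenset(
                _enum(Location, l, line_no, "location")
                for l in _split_list(row.get("locations", ""))
            ),
            is_tf=tf_cell == "1",
            tf_gene_count=count,
        )
        if tid in out and out[tid] != ann:
            raise ValidationError(f"target {tid}: conflicting duplicate rows")
        out[tid] = ann
    return out


def write_annotation_table(
    annotations: dict[str, TargetAnnotation], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for tid in sorted(annotations):
            a = annotations[tid]
            w.writerow(
                [
                    a.target_id,
                    a.name,
                    a.ttd_status.value,
                    LIST_SEP.join(sorted(a.diseases)),
                    LIST_SEP.join(a.domain_ids),
                    a.family.value,
                    LIST_SEP.join(sorted(l.value for l in a.locations)),
                    "1" if a.is_tf else "0",
                    a.tf_gene_count,
                ]
            )


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read a GMT gene-set file into :class:`PathwaySet` records.

    The category is the token ``disease`` (or ``basic``) in the
    description field; anything else defaults to basic.  Duplicate
    member ids on a line are deduplicated.
    """
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, need >=3", line_no
                )
            pid, desc = fields[0].strip(), fields[1].strip()
            tokens = {t.lower() for t in desc.split()}
            category = (
                PathwayCategory.DISEASE if "disease" in tokens else PathwayCategory.BASIC
            )
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"pathway {pid}: no members", line_no)
            out.append(PathwaySet(pid, desc, category, members))
    return out


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in sorted(pathways, key=lambda p: p.pathway_id):
            desc = p.name
            if p.category.value not in desc.lower().split():
                desc = f"{p.category.value} {desc}".strip()
            fh.write("\t".join([p.pathway_id, desc, *sorted(p.members)]) + "\n")


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Cross-check a dataset without mutating it.

    Reports dangling target references (compound or pathway members with
    no annotation record), duplicate compound/pathway ids, and a
    ``universe_size`` smaller than the number of annotated targets.
    """
    report = ValidationReport()
    annotated = set(dataset.annotations)
    referenced: set[str] = set()
    seen_cids: set[str] = set()
    for c in dataset.compounds:
        if c.compound_id in seen_cids:
            report.duplicate_ids.append(c.compound_id)
        seen_cids.add(c.compound_id)
        referenced |= c.all_targets
    seen_pids: set[str] = set()
    for p in dataset.pathways:
        if p.pathway_id in seen_pids:
            report.duplicate_ids.append(p.pathway_id)
        seen_pids.add(p.pathway_id)
        referenced |= p.members
    report.dangling_targets = sorted(referenced - annotated)
    if dataset.universe_size < len(annotated):
        report.universe_violations.append(
            f"universe_size {dataset.universe_size} < {len(annotated)} annotated targets"
        )
    return report


def load_dataset(
    compounds_path: str | Path,
    annotations_path: str | Path,
    gmt_path: str | Path | None = None,
    universe_size: int | None = None,
) -> Dataset:
    """Convenience loader assembling a :class:`Dataset` from fixture files."""
    annotations = read_annotation_table(annotations_path)
    ds = Dataset(
        compounds=read_compound_table(compounds_path),
        annotations=annotations,
        pathways=read_gmt(gmt_path) if gmt_path else [],
        universe_size=universe_size if universe_size else max(20_000, len(annotations)),
    )
    return ds
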