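"""Core domain types for the drug/herbal-ingredient target comparison.

The vocabulary mirrors the curated databases the analysis draws on:
Therapeutic Target Database stage labels (``TTDStatus``), UniProt-style
biochemical families, GO-derived subcellular compartments, and the
direct/indirect split that herb-target databases make for ingredient
targets (a direct target is bound/modulated by the compound itself; an
indirect one is regulated downstream).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable


class CompoundClass(str, enum.Enum):
    HERBAL_INGREDIENT = "herbal_ingredient"
    WESTERN_DRUG = "western_drug"


class LinkType(str, enum.Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"


class TTDStatus(str, enum.Enum):
    """Therapeutic Target Database development stage; ``ABSENT`` marks a
    target with no TTD record (kept explicit so tally denominators are
    unambiguous)."""

    SUCCESSFUL = "successful"
    CLINICAL_TRIAL = "clinical_trial"
    RESEARCH = "research"
    DISCONTINUED = "discontinued"
    ABSENT = "absent"


#: statuses counted as "in TTD" (everything except ABSENT)
IN_TTD_STATUSES = (
    TTDStatus.SUCCESSFUL,
    TTDStatus.CLINICAL_TRIAL,
    TTDStatus.RESEARCH,
    TTDStatus.DISCONTINUED,
)


class ProteinFamily(str, enum.Enum):
    ENZYME = "enzyme"
    CHANNEL_TRANSPORTER = "channel_transporter"
    RECEPTOR = "receptor"
    FACTOR_REGULATOR = "factor_regulator"
    STRUCTURE = "structure"
    BINDING = "binding"
    OTHER = "other"


class Location(str, enum.Enum):
    PLASMA_MEMBRANE = "plasma_membrane"
    CYTOPLASM = "cytoplasm"
    NUCLEUS = "nucleus"
    BLOOD = "blood"
    OTHER = "other"


class PathwayCategory(str, enum.Enum):
    BASIC = "basic"
    DISEASE = "disease"


class Effect(str, enum.Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"


class Position(str, enum.Enum):
    """Position of a node in a disease signalling cascade: receptor-proximal
    (upstream) vs effector-proximal (downstream)."""

    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UNASSIGNED = "unassigned"


class CardionetError(Exception):
    """Base class for package errors."""


class SchemaError(CardionetError):
    """A required column is missing or the header does not match."""


class ParseError(CardionetError):
    """A cell could not be parsed; carries the 1-based source line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class ValidationError(CardionetError):
    """Structurally valid input that violates a dataset invariant."""


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero (half-up), the convention used for
    every printed percentage and ratio (e.g. 2.375 -> 2.38 at 2 decimals).

    Goes through ``str`` so the shortest decimal representation of the
    float, not its binary expansion, is what gets rounded.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Compound:
    """A western drug or herbal ingredient with its target links.

    Western drugs carry only direct links; the direct/indirect split
    exists only for herbal ingredients (their database distinguishes
    directly bound targets from downstream-regulated ones).
    """

    compound_id: str
    name: str
    compound_class: CompoundClass
    target_links: list[tuple[str, LinkType]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        seen = set()
        for link in self.target_links:
            if link in seen:
                raise ValidationError(
                    f"compound {self.compound_id}: duplicate link {link}"
                )
            seen.add(link)
        if self.compound_class is CompoundClass.WESTERN_DRUG:
            bad = [t for t, lt in self.target_links if lt is not LinkType.DIRECT]
            if bad:
                raise ValidationError(
                    f"western drug {self.compound_id} has indirect links: {bad}"
                )

    @property
    def direct_targets(self) -> set[str]:
        return {t for t, lt in self.target_links if lt is LinkType.DIRECT}

    @property
    def all_targets(self) -> set[str]:
        return {t for t, _ in self.target_links}


@dataclass
class TargetAnnotation:
    """Per-protein annotation record.

    ``tf_gene_count`` (number of known transcriptional genes) is
    independent of ``is_tf``: curated TF lists contain factors with zero
    recorded transcriptional genes.
    """

    target_id: str
    name: str = ""
    ttd_status: TTDStatus = TTDStatus.ABSENT
    diseases: frozenset[str] = frozenset()
    domain_ids: tuple[str, ...] = ()
    family: ProteinFamily = ProteinFamily.OTHER
    locations: frozenset[Location] = frozenset()
    is_tf: bool = False
    tf_gene_count: int = 0

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValidationError("target_id must be non-empty")
        if self.tf_gene_count < 0:
            raise ValidationError(
                f"{self.target_id}: tf_gene_count must be non-negative"
            )
        self.diseases = frozenset(self.diseases)
        self.domain_ids = tuple(self.domain_ids)
        self.locations = frozenset(Location(l) for l in self.locations)

    @property
    def disease_count(self) -> int:
        return len(self.diseases)


@dataclass
class PathwaySet:
    """A named gene set (pathway) with a basic/disease category flag."""

    pathway_id: str
    name: str
    category: PathwayCategory = PathwayCategory.BASIC
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.category = PathwayCategory(self.category)
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id}: empty member set")


@dataclass
class Dataset:
    """Aggregate container tying compounds, annotations and pathways
    together, with the background proteome size used for enrichment."""

    compounds: list[Compound] = field(default_factory=list)
    annotations: dict[str, TargetAnnotation] = field(default_factory=dict)
    pathways: list[PathwaySet] = field(default_factory=list)
    universe_size: int = 20_000

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)


@dataclass
class ValidationReport:
    """Problems found by :func:`cardionet.io.validate_dataset`; an empty
    report means the dataset is internally consistent."""

    dangling_targets: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    universe_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.dangling_targets or self.duplicate_ids or self.universe_violations
        )

    def entries(self) -> list[str]:
        out = [f"dangling target reference: {t}" for t in self.dangling_targets]
        out += [f"duplicate id: {i}" for i in self.duplicate_ids]
        out += self.universe_violations
        return out


def class_target_sets(compounds: Iterable[Compound]) -> dict[str, set[str]]:
    """Pool per-class target sets from compound link tables.

    Returns keys ``western`` (all western-drug targets, necessarily
    direct), ``herbal_direct`` and ``herbal_all`` (direct+indirect) —
    the three groups the comparative tables are computed over.
    """
    western: set[str] = set()
    herbal_direct: set[str] = set()
    herbal_all: set[str] = set()
    for c in compounds:
        if c.compound_class is CompoundClass.WESTERN_DRUG:
            western |= c.all_targets
        else:
            herbal_direct |= c.direct_targets
            herbal_all |= c.all_targets
    return {
        "western": western,
        "herbal_direct": herbal_direct,
        "herbal_all": herbal_all,
    }
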