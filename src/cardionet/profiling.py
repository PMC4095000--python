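"""Target-level comparative statistics between compound classes.

Covers the development-stage census of a target group against the
Therapeutic Target Database (tally), the d/t statistic (average number
of associated diseases per target, computed per TTD stage), domain-count
/ family / subcellular-location distributions, transcription-factor
enrichment against a proteome background, and a coarse classifier of
multi-target compounds (same family vs same biological process).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .enrichment import ContingencyTable2x2, fisher_right_tail
from .types import (
    CardionetError,
    Compound,
    IN_TTD_STATUSES,
    Location,
    PathwaySet,
    ProteinFamily,
    TargetAnnotation,
    TTDStatus,
    round_half_up,
)

#: Proteome-scale background for the TF test.  The human proteome is
#: taken as 20,000 proteins; 618 is the number of transcription factors
#: catalogued in TRANSFAC.
DEFAULT_TF_UNIVERSE = 20_000
DEFAULT_TF_COUNT = 618

#: d/t is reported for these stages only (discontinued targets are kept
#: in tallies but carry too few disease records to be summarized).
DT_STATUSES = (TTDStatus.SUCCESSFUL, TTDStatus.CLINICAL_TRIAL, TTDStatus.RESEARCH)


@dataclass(frozen=True)
class CategoryTally:
    """Per-group census of TTD development stages with percentages
    (half-up, one decimal)."""

    group_label: str
    denominator: int
    per_status_count: dict[TTDStatus, int]
    per_status_pct: dict[TTDStatus, float]
    in_ttd_count: int
    in_ttd_pct: float


@dataclass(frozen=True)
class DTStatistic:
    """Average diseases per target for one group × TTD stage.

    ``n_disease_associations`` sums each target's own disease count;
    a disease shared by two targets is counted twice (this is the
    association count, not the size of the union of disease names).
    """

    group_label: str
    ttd_status: TTDStatus
    n_targets: int
    n_disease_associations: int
    dt_value: float


class ProfileAxis(str, enum.Enum):
    DOMAIN_COUNT = "domain_count"
    FAMILY = "family"
    LOCATION = "location"


@dataclass(frozen=True)
class DistributionProfile:
    group_label: str
    axis: ProfileAxis
    bins: tuple[tuple[str, int, float], ...]  # (label, count, fraction)


@dataclass(frozen=True)
class TFEnrichment:
    group_label: str
    n_targets: int
    n_tf_targets: int
    universe_size: int
    n_tf_universe: int
    p_value: float


class MultiTargetClass(str, enum.Enum):
    SINGLE_TARGET = "single_target"
    SAME_FAMILY_MULTI = "same_family_multi"
    SAME_PROCESS_MULTI = "same_process_multi"
    OTHER = "other"


def _require_annotations(
    targets: Iterable[str], annotations: Mapping[str, TargetAnnotation]
) -> list[TargetAnnotation]:
    missing = [t for t in targets if t not in annotations]
    if missing:
        raise CardionetError(f"missing annotations for: {sorted(missing)[:5]} ...")
    return [annotations[t] for t in sorted(set(targets))]


def tally_ttd(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
) -> CategoryTally:
    """Count a target group by TTD development stage.

    Percentages are over the full group (the denominator includes
    targets absent from TTD) and follow the half-up convention.
    """
    if not targets:
        raise CardionetError("tally_ttd: empty target set")
    anns = _require_annotations(targets, annotations)
    denom = len(anns)
    counts = {s: 0 for s in TTDStatus}
    for a in anns:
        counts[a.ttd_status] += 1
    in_ttd = sum(counts[s] for s in IN_TTD_STATUSES)
    pct = {s: round_half_up(100.0 * counts[s] / denom, 1) for s in TTDStatus}
    return CategoryTally(
        group_label=group_label,
        denominator=denom,
        per_status_count=counts,
        per_status_pct=pct,
        in_ttd_count=in_ttd,
        in_ttd_pct=round_half_up(100.0 * in_ttd / denom, 1),
    )


def compute_dt(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    status: TTDStatus,
    group_label: str,
) -> DTStatistic:
    """d/t for the targets of *status* within a group: total disease
    associations divided by the number of targets (exact; rounding only
    at reporting time)."""
    anns = [a for a in _require_annotations(targets, annotations) if a.ttd_status is status]
    if not anns:
        raise CardionetError(f"no targets with status {status.value} in group")
    n_assoc = sum(a.disease_count for a in anns)
    return DTStatistic(
        group_label=group_label,
        ttd_status=status,
        n_targets=len(anns),
        n_disease_associations=n_assoc,
        dt_value=n_assoc / len(anns),
    )


def dt_table(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
) -> list[DTStatistic]:
    """d/t rows for the three reported stages, skipping stages with no
    targets in the group."""
    rows = []
    for status in DT_STATUSES:
        try:
            rows.append(compute_dt(targets, annotations, status, group_label))
        except CardionetError:
            continue
    return rows


def domain_count_profile(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
) -> DistributionProfile:
    """Distribution of structure-domain counts: each target falls into the
    integer bin given by the length of its domain list (a proxy for the
    functional complexity of the protein)."""
    anns = _require_annotations(targets, annotations)
    counts: dict[int, int] = {}
    for a in anns:
        counts[len(a.domain_ids)] = counts.get(len(a.domain_ids), 0) + 1
    n = len(anns)
    bins = tuple(
        (str(k), counts[k], counts[k] / n) for k in sorted(counts)
    )
    return DistributionProfile(group_label, ProfileAxis.DOMAIN_COUNT, bins)


def family_profile(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
) -> DistributionProfile:
    """Biochemical family distribution; each target counted exactly once
    (targets without a family fall under ``other``)."""
    anns = _require_annotations(targets, annotations)
    counts = {f: 0 for f in ProteinFamily}
    for a in anns:
        counts[a.family] += 1
    n = len(anns)
    bins = tuple((f.value, counts[f], counts[f] / n) for f in ProteinFamily)
    return DistributionProfile(group_label, ProfileAxis.FAMILY, bins)


def location_profile(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
) -> DistributionProfile:
    """Subcellular-location distribution; a target with k annotated
    compartments contributes one count to each, so fractions (over the
    number of targets) can sum above 1."""
    anns = _require_annotations(targets, annotations)
    counts = {l: 0 for l in Location}
    for a in anns:
        for loc in a.locations:
            counts[loc] += 1
    n = len(anns)
    bins = tuple((l.value, counts[l], counts[l] / n) for l in Location)
    return DistributionProfile(group_label, ProfileAxis.LOCATION, bins)


def tf_enrichment(
    targets: set[str],
    annotations: Mapping[str, TargetAnnotation],
    group_label: str,
    universe_size: int = DEFAULT_TF_UNIVERSE,
    n_tf_universe: int = DEFAULT_TF_COUNT,
) -> TFEnrichment:
    """Right-tail Fisher test for transcription-factor over-representation
    in a target group against a proteome background."""
    anns = _require_annotations(targets, annotations)
    n = len(anns)
    if universe_size < n:
        raise CardionetError("universe_size smaller than the target group")
    n_tf = sum(a.is_tf for a in anns)
    if n_tf > n_tf_universe:
        warnings.warn(
            f"{group_label}: observed {n_tf} TFs exceeds background TF count "
            f"{n_tf_universe}; background inflated to the observed count",
            stacklevel=2,
        )
        n_tf_universe = n_tf
    table = ContingencyTable2x2(
        a=n_tf,
        b=n - n_tf,
        c=n_tf_universe - n_tf,
        d=universe_size - n_tf_universe - (n - n_tf),
    )
    return TFEnrichment(group_label, n, n_tf, universe_size, n_tf_universe, fisher_right_tail(table))


def classify_multitarget_compounds(
    compounds: Iterable[Compound],
    annotations: Mapping[str, TargetAnnotation],
    pathways: Sequence[PathwaySet],
) -> dict[str, MultiTargetClass]:
    """Coarse drug-type classification by direct-target structure.

    Precedence: exactly one distinct target -> ``single_target``; all
    targets in one biochemical family -> ``same_family_multi`` (different
    subtypes of one protein type); otherwise all targets co-occurring in
    at least one common pathway -> ``same_process_multi``; else ``other``.
    """
    out: dict[str, MultiTargetClass] = {}
    for c in compounds:
        targets = c.direct_targets
        if not targets:
            warnings.warn(f"compound {c.compound_id}: no direct targets", stacklevel=2)
            out[c.compound_id] = MultiTargetClass.OTHER
            continue
        if len(targets) == 1:
            out[c.compound_id] = MultiTargetClass.SINGLE_TARGET
            continue
        families = {annotations[t].family for t in targets if t in annotations}
        if len(families) == 1 and len(targets) == len(
            [t for t in targets if t in annotations]
        ):
            out[c.compound_id] = MultiTargetClass.SAME_FAMILY_MULTI
            continue
        if any(targets <= p.members for p in pathways):
            out[c.compound_id] = MultiTargetClass.SAME_PROCESS_MULTI
        else:
            out[c.compound_id] = MultiTargetClass.OTHER
    return out


def write_profile_table(profile: DistributionProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\taxis\tbin\tcount\tfraction\n")
        for label, count, frac in profile.bins:
            fh.write(f"{profile.group_label}\t{profile.axis.value}\t{label}\t{count}\t{frac:.6g}\n")
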