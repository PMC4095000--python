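"""One-sided Fisher's exact test and pathway over-representation.

The test asks whether a target set hits a pathway more often than a
uniform draw from the background universe would.  With the 2x2 table

====================  ============  ================
.                      in pathway    not in pathway
====================  ============  ================
in target set          a             b
not in target set      c             d
====================  ============  ================

the right-tail p-value is ``P(X >= a)`` for ``X ~ Hypergeometric(N=a+b+c+d,
K=a+c, n=a+b)``.  Terms are accumulated from log-gamma factorials so the
tail is exact to ~1e-12 relative error for the population sizes that occur
here.  Significance uses the strict threshold ``p < alpha`` with
``alpha = 0.01`` by default; no multiple-testing correction is applied by
default (an optional Benjamini–Hochberg mode is provided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .types import (
    CardionetError,
    Compound,
    PathwayCategory,
    PathwaySet,
    TargetAnnotation,
)

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) with a = in-set ∧ in-pathway."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CardionetError("contingency counts must be non-negative")
        if self.n == 0:
            raise CardionetError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    entity_id: str
    pathway_id: str
    table: ContingencyTable2x2
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_right_tail(table: ContingencyTable2x2) -> float:
    """Right-tail (enrichment) Fisher p-value for a 2x2 table.

    Sums hypergeometric point probabilities from the observed ``a``
    up to ``min(a+b, a+c)`` in log space.  Returns exactly 1.0 when
    ``a`` sits at the lower end of the support.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N, K, n = table.n, a + c, a + b
    if n == 0 or K == 0:
        raise CardionetError("degenerate margins: a+b and a+c must be positive")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if a <= lo:
        return 1.0
    log_denom = _log_comb(N, n)
    # sum small->large: terms beyond the mode decay, so accumulate from hi down
    total = 0.0
    for x in range(hi, a - 1, -1):
        total += math.exp(_log_comb(K, x) + _log_comb(N - K, n - x) - log_denom)
    return min(total, 1.0)


def enrich_pathways(
    target_set: set[str],
    pathways: Sequence[PathwaySet],
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
    entity_id: str = "target_set",
    universe_size: int | None = None,
) -> list[EnrichmentResult]:
    """Test each pathway for over-representation of *target_set*.

    Pathway members are intersected with *universe* before testing;
    pathways with no member in the universe are skipped.  *universe_size*
    may inflate the background beyond ``len(universe)`` (the extra
    proteins count as outside both set and pathway).  Results are sorted
    by ascending p-value, ties broken by pathway id.
    """
    if not universe:
        raise CardionetError("empty universe")
    if not target_set:
        raise CardionetError("empty target set")
    if not target_set <= universe:
        raise CardionetError("target_set must be a subset of the universe")
    n_bg = universe_size if universe_size is not None else len(universe)
    if n_bg < len(universe):
        raise CardionetError("universe_size smaller than the explicit universe")
    results = []
    for p in pathways:
        members = p.members & universe
        if not members:
            continue
        a = len(target_set & members)
        b = len(target_set) - a
        c = len(members) - a
        d = n_bg - a - b - c
        table = ContingencyTable2x2(a, b, c, d)
        pval = fisher_right_tail(table)
        results.append(
            EnrichmentResult(entity_id, p.pathway_id, table, pval, pval < alpha, alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def enrich_per_compound(
    compounds: Iterable[Compound],
    annotations: Mapping[str, TargetAnnotation],
    pathways: Sequence[PathwaySet],
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, list[EnrichmentResult]]:
    """Per-compound enrichment over each compound's direct targets.

    Compounds with no direct target inside the universe are skipped with
    a warning.
    """
    out: dict[str, list[EnrichmentResult]] = {}
    for c in compounds:
        targets = c.direct_targets & universe
        if not targets:
            warnings.warn(
                f"compound {c.compound_id}: no direct target in universe, skipped",
                stacklevel=2,
            )
            continue
        out[c.compound_id] = enrich_pathways(
            targets, pathways, universe, alpha, entity_id=c.compound_id
        )
    return out


def split_basic_disease(
    items: Sequence[PathwaySet] | Sequence[EnrichmentResult],
    pathway_index: Mapping[str, PathwaySet] | None = None,
) -> tuple[list, list, float]:
    """Partition pathways (or enrichment results) into basic vs disease.

    Returns ``(basic, disease, disease_fraction)``.  Enrichment results
    need *pathway_index* to resolve categories.
    """
    if not items:
        raise CardionetError("empty input to split_basic_disease")

    def category(item) -> PathwayCategory:
        if isinstance(item, PathwaySet):
            return item.category
        if pathway_index is None:
            raise CardionetError(
                "pathway_index required to split enrichment results"
            )
        return pathway_index[item.pathway_id].category

    basic = [i for i in items if category(i) is PathwayCategory.BASIC]
    disease = [i for i in items if category(i) is PathwayCategory.DISEASE]
    return basic, disease, len(disease) / len(items)


def apply_benjamini_hochberg(
    results: Sequence[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Optional FDR mode: recompute significance flags by Benjamini–Hochberg.

    Off by default throughout the pipeline, which thresholds raw p-values.
    """
    if not results:
        return []
    reject, _, _, _ = multipletests(
        [r.p_value for r in results], alpha=alpha, method="fdr_bh"
    )
    return [replace(r, significant=bool(rej), alpha=alpha) for r, rej in zip(results, reject)]


def make_universe(
    mode: str,
    pathways: Sequence[PathwaySet] = (),
    annotations: Mapping[str, TargetAnnotation] | None = None,
) -> set[str]:
    """Resolve the enrichment background: ``pathway-union`` (default
    convention) or ``annotated`` (all annotated targets)."""
    if mode == "pathway-union":
        out: set[str] = set()
        for p in pathways:
            out |= p.members
        return out
    if mode == "annotated":
        if annotations is None:
            raise CardionetError("annotated universe requires annotations")
        return set(annotations)
    raise CardionetError(f"unknown universe mode {mode!r}")


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path
) -> None:
    """TSV export: entity, pathway, 2x2 counts, p (6 sig figs), flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tpathway_id\ta\tb\tc\td\tp_value\tsignificant\n")
        for r in results:
            t = r.table
            fh.write(
                f"{r.entity_id}\t{r.pathway_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{r.p_value:.6g}\t{int(r.significant)}\n"
            )
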