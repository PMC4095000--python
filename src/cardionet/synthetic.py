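"""Synthetic datasets with the statistical structure the analysis assumes.

Two generators and one deterministic fixture:

* :func:`generate_dataset` draws a two-class compound/target world with
  planted class differences — disease-association means (the d/t gap),
  TF fractions, family/location biases, and a handful of pathways whose
  membership odds are inflated for one class (planted enrichment);
* :func:`generate_subnetwork` draws a disease subnetwork whose regulated
  nodes have class-specific upstream/downstream biases;
* :func:`paper_fixture` is a deterministic dataset that realizes, at the
  margin level, the published census of anti-CVD drug/ingredient targets
  (stage tallies, per-stage disease-association totals, and the two TF
  lists), so the profiling stages can be checked against printed values
  without any database download.  Individual disease identities are
  synthetic labels; only the marginal counts are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .disease import DiseaseSubnetwork, NodeInfo, annotate_regulators, assemble_subnetwork
from .io import read_compound_table
from .types import (
    CardionetError,
    Compound,
    CompoundClass,
    Dataset,
    Effect,
    LinkType,
    Location,
    PathwayCategory,
    PathwaySet,
    Position,
    ProteinFamily,
    TargetAnnotation,
    TTDStatus,
)

HERBAL = "herbal"
WESTERN = "western"

_FAMILIES = list(ProteinFamily)
_LOCATIONS = list(Location)

#: stage proportions used to draw TTD statuses, echoing the published
#: census shape (successful, clinical_trial, research, discontinued, absent)
DEFAULT_STATUS_PROBS = {
    WESTERN: (0.397, 0.074, 0.142, 0.010, 0.377),
    HERBAL: (0.271, 0.085, 0.271, 0.025, 0.348),
}

# family order: enzyme, channel_transporter, receptor, factor_regulator,
# structure, binding, other
DEFAULT_FAMILY_WEIGHTS = {
    HERBAL: (0.40, 0.08, 0.12, 0.22, 0.04, 0.08, 0.06),
    WESTERN: (0.18, 0.28, 0.32, 0.08, 0.04, 0.06, 0.04),
}
# location order: plasma_membrane, cytoplasm, nucleus, blood, other
DEFAULT_LOCATION_WEIGHTS = {
    HERBAL: (0.15, 0.40, 0.30, 0.05, 0.10),
    WESTERN: (0.50, 0.25, 0.10, 0.08, 0.07),
}


@dataclass
class SyntheticConfig:
    """Knobs for the planted-structure generator.

    Defaults encode the study conditions the comparative analysis was
    designed around: 200 targets per class (20 shared), 50 compounds per
    class, 50 pathways with 5 planted at membership-odds ratio 8,
    disease-count means 5.0 (herbal) vs 2.5 (western), TF fractions at
    the published 11/118 and 10/204, and downstream-position biases
    0.8 (herbal) vs 0.2 (western).
    """

    seed: int = 0
    n_targets_per_class: int = 200
    n_shared_targets: int = 20
    n_compounds_per_class: int = 50
    targets_per_compound_mean: float = 3.0
    herbal_indirect_fraction: float = 0.3
    n_pathways: int = 50
    pathway_size_mean: float = 20.0
    n_planted_enriched: int = 5
    enrichment_odds: float = 8.0
    disease_count_mean: dict = field(
        default_factory=lambda: {HERBAL: 5.0, WESTERN: 2.5}
    )
    tf_fraction: dict = field(
        default_factory=lambda: {HERBAL: 11 / 118, WESTERN: 10 / 204}
    )
    domain_count_mean: dict = field(
        default_factory=lambda: {HERBAL: 2.5, WESTERN: 1.5}
    )
    family_weights: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS))
    location_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_WEIGHTS)
    )
    status_probs: dict = field(default_factory=lambda: dict(DEFAULT_STATUS_PROBS))
    position_bias: dict = field(default_factory=lambda: {HERBAL: 0.8, WESTERN: 0.2})
    subnetwork_nodes: int = 100
    subnetwork_regulated_fraction: float = 0.45

    def validate(self) -> None:
        for d in (self.family_weights, self.location_weights, self.status_probs):
            for w in d.values():
                if abs(sum(w) - 1.0) > 1e-9:
                    raise CardionetError("weights must sum to 1")
        for p in (*self.tf_fraction.values(), *self.position_bias.values()):
            if not 0.0 <= p <= 1.0:
                raise CardionetError("probabilities must lie in [0,1]")
        if self.n_planted_enriched > self.n_pathways:
            raise CardionetError("more planted pathways than pathways")
        if self.n_shared_targets > self.n_targets_per_class:
            raise CardionetError("shared targets exceed class size")
        if self.pathway_size_mean > 2 * self.n_targets_per_class:
            raise CardionetError("pathway sizes exceed the target pool")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    planted_pathway_ids: list[str]
    herbal_targets: list[str]
    western_targets: list[str]
    dt_mean: dict[str, float]  # expected disease-count mean per class pool
    tf_fraction: dict[str, float]
    position_bias: dict[str, float]
    family_weights: dict[str, tuple]
    enrichment_odds: float


def _mix(a: float, b: float) -> float:
    return 0.5 * (a + b)


def _mean_for(config: SyntheticConfig, param: dict, cls: str) -> float:
    # shared targets are drawn from the midpoint of the two class settings
    if cls == "shared":
        return _mix(param[HERBAL], param[WESTERN])
    return param[cls]


def _draw_annotation(
    rng: np.random.Generator, config: SyntheticConfig, tid: str, cls: str
) -> TargetAnnotation:
    if cls == "shared":
        status_p = tuple(
            _mix(a, b)
            for a, b in zip(config.status_probs[HERBAL], config.status_probs[WESTERN])
        )
        fam_w = tuple(
            _mix(a, b)
            for a, b in zip(config.family_weights[HERBAL], config.family_weights[WESTERN])
        )
        loc_w = tuple(
            _mix(a, b)
            for a, b in zip(
                config.location_weights[HERBAL], config.location_weights[WESTERN]
            )
        )
    else:
        status_p = config.status_probs[cls]
        fam_w = config.family_weights[cls]
        loc_w = config.location_weights[cls]
    status = [
        TTDStatus.SUCCESSFUL,
        TTDStatus.CLINICAL_TRIAL,
        TTDStatus.RESEARCH,
        TTDStatus.DISCONTINUED,
        TTDStatus.ABSENT,
    ][rng.choice(5, p=np.asarray(status_p) / sum(status_p))]
    n_dis = rng.poisson(_mean_for(config, config.disease_count_mean, cls))
    n_dom = rng.poisson(_mean_for(config, config.domain_count_mean, cls))
    is_tf = rng.random() < _mean_for(config, config.tf_fraction, cls)
    fam = _FAMILIES[rng.choice(len(_FAMILIES), p=np.asarray(fam_w) / sum(fam_w))]
    n_loc = 1 + (rng.random() < 0.3)
    locs = rng.choice(len(_LOCATIONS), size=n_loc, replace=False, p=np.asarray(loc_w) / sum(loc_w))
    return TargetAnnotation(
        target_id=tid,
        name=f"protein {tid}",
        ttd_status=status,
        diseases=frozenset(f"dis:{tid}:{i}" for i in range(n_dis)),
        domain_ids=tuple(f"PF{rng.integers(10_000, 99_999)}" for _ in range(n_dom)),
        family=fam,
        locations=frozenset(_LOCATIONS[i] for i in locs),
        is_tf=bool(is_tf),
        tf_gene_count=int(rng.poisson(5.0)) if is_tf else 0,
    )


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a dataset with planted class differences; reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_only = config.n_targets_per_class - config.n_shared_targets
    herbal_only = [f"H{i:05d}" for i in range(n_only)]
    western_only = [f"W{i:05d}" for i in range(n_only)]
    shared = [f"S{i:05d}" for i in range(config.n_shared_targets)]
    herbal_pool = herbal_only + shared
    western_pool = western_only + shared
    all_targets = herbal_only + western_only + shared

    annotations = {}
    for tid in herbal_only:
        annotations[tid] = _draw_annotation(rng, config, tid, HERBAL)
    for tid in western_only:
        annotations[tid] = _draw_annotation(rng, config, tid, WESTERN)
    for tid in shared:
        annotations[tid] = _draw_annotation(rng, config, tid, "shared")

    compounds: list[Compound] = []
    for cls, pool, prefix in (
        (CompoundClass.HERBAL_INGREDIENT, herbal_pool, "HERB"),
        (CompoundClass.WESTERN_DRUG, western_pool, "WDRUG"),
    ):
        for i in range(config.n_compounds_per_class):
            k = 1 + rng.poisson(max(config.targets_per_compound_mean - 1.0, 0.0))
            k = min(k, len(pool))
            picks = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
            links = []
            for t in picks:
                indirect = (
                    cls is CompoundClass.HERBAL_INGREDIENT
                    and rng.random() < config.herbal_indirect_fraction
                )
                links.append((t, LinkType.INDIRECT if indirect else LinkType.DIRECT))
            compounds.append(Compound(f"{prefix}{i:04d}", f"{prefix.lower()} {i}", cls, links))

    herbal_set = set(herbal_pool)
    n_total = len(all_targets)
    pathways: list[PathwaySet] = []
    planted_ids: list[str] = []
    for j in range(config.n_pathways):
        planted = j < config.n_planted_enriched
        size = max(3, rng.poisson(config.pathway_size_mean))
        p_base = min(size / n_total, 0.95)
        odds_base = p_base / (1.0 - p_base)
        odds_a = odds_base * (config.enrichment_odds if planted else 1.0)
        p_a = odds_a / (1.0 + odds_a)
        members = {
            t
            for t in all_targets
            if rng.random() < (p_a if t in herbal_set else p_base)
        }
        if not members:
            members = {all_targets[int(rng.integers(n_total))]}
        pid = f"PW{j:03d}"
        category = (
            PathwayCategory.DISEASE if j % 3 == 2 else PathwayCategory.BASIC
        )
        name = f"{category.value} synthetic pathway {j}"
        pathways.append(PathwaySet(pid, name, category, frozenset(members)))
        if planted:
            planted_ids.append(pid)

    share = config.n_shared_targets / config.n_targets_per_class
    truth = GroundTruth(
        planted_pathway_ids=planted_ids,
        herbal_targets=sorted(herbal_pool),
        western_targets=sorted(western_pool),
        dt_mean={
            cls: (1 - share) * config.disease_count_mean[cls]
            + share * _mix(*[config.disease_count_mean[c] for c in (HERBAL, WESTERN)])
            for cls in (HERBAL, WESTERN)
        },
        tf_fraction={
            cls: (1 - share) * config.tf_fraction[cls]
            + share * _mix(*[config.tf_fraction[c] for c in (HERBAL, WESTERN)])
            for cls in (HERBAL, WESTERN)
        },
        position_bias=dict(config.position_bias),
        family_weights={cls: tuple(w) for cls, w in config.family_weights.items()},
        enrichment_odds=config.enrichment_odds,
    )
    dataset = Dataset(
        compounds=compounds,
        annotations=annotations,
        pathways=pathways,
        universe_size=n_total,
    )
    return dataset, truth


def generate_subnetwork(config: SyntheticConfig, name: str = "synthetic") -> DiseaseSubnetwork:
    """Draw a disease subnetwork whose herbal/western-regulated nodes have
    the configured downstream-position biases; reproducible per seed."""
    rng = np.random.default_rng(config.seed + 1)
    n = config.subnetwork_nodes
    nodes: dict[str, NodeInfo] = {}
    regulators: dict[str, set[str]] = {}
    f = config.subnetwork_regulated_fraction
    for i in range(n):
        nid = f"N{i:04d}"
        u = rng.random()
        if u < f:
            cls = HERBAL
        elif u < 2 * f:
            cls = WESTERN
        else:
            cls = None
        if cls is None:
            p_down = 0.5
        else:
            p_down = config.position_bias[cls]
            regulators[nid] = {cls}
        position = Position.DOWNSTREAM if rng.random() < p_down else Position.UPSTREAM
        loc_w = (
            config.location_weights[cls]
            if cls
            else tuple(
                _mix(a, b)
                for a, b in zip(
                    config.location_weights[HERBAL], config.location_weights[WESTERN]
                )
            )
        )
        loc = _LOCATIONS[rng.choice(len(_LOCATIONS), p=np.asarray(loc_w) / sum(loc_w))]
        nodes[nid] = NodeInfo(loc, position)
    ids = sorted(nodes)
    edges = []
    for a, b in zip(ids[:-1], ids[1:]):  # spanning chain keeps it connected
        edges.append((a, b, Effect.ACTIVATION if rng.random() < 0.7 else Effect.INHIBITION))
    for _ in range(n // 2):
        i, j = rng.choice(n, size=2, replace=False)
        edges.append(
            (ids[i], ids[j], Effect.ACTIVATION if rng.random() < 0.7 else Effect.INHIBITION)
        )
    return DiseaseSubnetwork(name, nodes, edges, regulators)


# ---------------------------------------------------------------------------
# deterministic fixture realizing the published marginal counts


_WESTERN_TFS = [
    ("P10275", "AR", 3),
    ("P04150", "GR-alpha", 5),
    ("P08235", "MR", 0),
    ("P10827", "T3R-alpha", 4),
    ("P10828", "T3R-beta1", 5),
    ("P51843", "DAX1", 0),
]
_HERBAL_TFS = [
    ("P03372", "ER-alpha", 8),
    ("Q04206", "RelA", 12),
    ("Q00613", "HSF1", 1),
    ("Q09472", "p300", 15),
    ("P40763", "STAT3", 3),
    ("O75469", "PXR-1/SXR", 0),
    ("Q92731", "ER-beta", 1),
]
#: TFs targeted by both classes
_SHARED_TFS = [
    ("P05412", "c-Jun", 19),
    ("P35869", "AhR", 7),
    ("Q07869", "PPAR-alpha", 0),
    ("Q03181", "PPAR-beta", 1),
]


def _compose(total: int, n: int, base: int) -> list[int]:
    """Deterministic composition of *total* over *n* parts: *base* each
    plus one extra for the leading parts."""
    extra = total - base * n
    if extra < 0 or extra > n * max(base, 1) + n:
        # fall back to a flat split with remainder up front
        base, extra = divmod(total, n)
    out = [base + 1 if i < extra else base for i in range(n)]
    assert sum(out) == total
    return out


def _mk(tid, name, status, n_dis, family, locations, is_tf=False, tf_genes=0, n_dom=1):
    return TargetAnnotation(
        target_id=tid,
        name=name,
        ttd_status=status,
        diseases=frozenset(f"dis:{tid}:{i}" for i in range(n_dis)),
        domain_ids=tuple(f"PF{abs(hash(tid)) % 9000 + 1000:04d}.{k}" for k in range(n_dom)),
        family=family,
        locations=frozenset(locations),
        is_tf=is_tf,
        tf_gene_count=tf_genes,
    )


def paper_fixture() -> Dataset:
    """Deterministic dataset reproducing the published marginal counts.

    Realized margins: western drugs 204 targets with stage counts
    81/15/29/2 (127 in TTD) and stage disease-association totals
    221/45/56; herbal direct targets 118 with 32/10/32/3 (77 in TTD) and
    160/39/76; herbal all targets 862 with 358 in TTD; 10 western and 11
    herbal TF targets with the published per-TF transcriptional-gene
    counts, four TFs shared between the classes.  The published
    per-stage component rows of the all-targets group (sum 366) are
    internally inconsistent with the published in-TTD sum (358); this
    fixture realizes the sum, absorbing the difference into the
    research-stage count (172 instead of 180), whose percentage is not
    part of the reproduced cells.  Disease identities, family/location/
    domain assignments and compound groupings are synthetic.
    """
    S, C, R, D, A = (
        TTDStatus.SUCCESSFUL,
        TTDStatus.CLINICAL_TRIAL,
        TTDStatus.RESEARCH,
        TTDStatus.DISCONTINUED,
        TTDStatus.ABSENT,
    )
    ann: dict[str, TargetAnnotation] = {}
    fr = ProteinFamily.FACTOR_REGULATOR
    nuc = [Location.NUCLEUS]

    for tid, name, genes in _SHARED_TFS:
        ann[tid] = _mk(tid, name, S, 2, fr, nuc, is_tf=True, tf_genes=genes, n_dom=2)

    # --- western drug targets: 204 = 4 shared + 6 TFs + 194 plain -------
    w_succ_ids = [t for t, _, _ in _WESTERN_TFS] + [f"WT{i:03d}" for i in range(71)]
    w_clin_ids = [f"WT{i:03d}" for i in range(71, 86)]
    w_res_ids = [f"WT{i:03d}" for i in range(86, 115)]
    w_disc_ids = [f"WT{i:03d}" for i in range(115, 117)]
    w_abs_ids = [f"WT{i:03d}" for i in range(117, 194)]
    w_fams = [
        ProteinFamily.RECEPTOR,
        ProteinFamily.CHANNEL_TRANSPORTER,
        ProteinFamily.RECEPTOR,
        ProteinFamily.ENZYME,
        ProteinFamily.CHANNEL_TRANSPORTER,
    ]
    tf_meta = {t: (n, g) for t, n, g in _WESTERN_TFS}
    for ids, status, counts in (
        (w_succ_ids, S, _compose(221 - 8, 77, 2)),
        (w_clin_ids, C, _compose(45, 15, 3)),
        (w_res_ids, R, _compose(56, 29, 1)),
        (w_disc_ids, D, [0, 0]),
        (w_abs_ids, A, [0] * 77),
    ):
        for i, tid in enumerate(ids):
            if tid in tf_meta:
                name, genes = tf_meta[tid]
                ann[tid] = _mk(tid, name, status, counts[i], fr, nuc, True, genes, 2)
            else:
                fam = w_fams[i % len(w_fams)]
                locs = (
                    [Location.PLASMA_MEMBRANE]
                    if fam in (ProteinFamily.RECEPTOR, ProteinFamily.CHANNEL_TRANSPORTER)
                    else [Location.CYTOPLASM]
                )
                ann[tid] = _mk(tid, f"western target {tid}", status, counts[i], fam, locs, n_dom=1 + i % 2)

    # --- herbal direct targets: 118 = 4 shared + 7 TFs + 107 plain ------
    h_succ_ids = [t for t, _, _ in _HERBAL_TFS] + [f"HD{i:03d}" for i in range(21)]
    h_clin_ids = [f"HD{i:03d}" for i in range(21, 31)]
    h_res_ids = [f"HD{i:03d}" for i in range(31, 63)]
    h_disc_ids = [f"HD{i:03d}" for i in range(63, 66)]
    h_abs_ids = [f"HD{i:03d}" for i in range(66, 107)]
    h_fams = [
        ProteinFamily.ENZYME,
        ProteinFamily.FACTOR_REGULATOR,
        ProteinFamily.ENZYME,
        ProteinFamily.RECEPTOR,
        ProteinFamily.BINDING,
    ]
    tf_meta = {t: (n, g) for t, n, g in _HERBAL_TFS}
    for ids, status, counts in (
        (h_succ_ids, S, _compose(160 - 8, 28, 5)),
        (h_clin_ids, C, _compose(39, 10, 3)),
        (h_res_ids, R, _compose(76, 32, 2)),
        (h_disc_ids, D, [0] * 3),
        (h_abs_ids, A, [0] * 41),
    ):
        for i, tid in enumerate(ids):
            if tid in tf_meta:
                name, genes = tf_meta[tid]
                ann[tid] = _mk(tid, name, status, counts[i], fr, nuc, True, genes, 3)
            else:
                fam = h_fams[i % len(h_fams)]
                locs = (
                    [Location.CYTOPLASM, Location.NUCLEUS]
                    if fam in (ProteinFamily.ENZYME, ProteinFamily.FACTOR_REGULATOR)
                    else [Location.CYTOPLASM]
                )
                ann[tid] = _mk(tid, f"herbal direct target {tid}", status, counts[i], fam, locs, n_dom=1 + i % 3)

    # --- herbal indirect targets: 744, chosen so the all-target group ---
    # --- realizes the printed in-TTD sum of 358 (84/88/172/14 + absent) -
    hi_counts = {S: 52, C: 78, R: 140, D: 11, A: 463}
    hi_dis = {S: 2, C: 2, R: 1, D: 0, A: 0}
    hi_ids: list[tuple[str, TTDStatus]] = []
    i = 0
    for status in (S, C, R, D, A):
        for _ in range(hi_counts[status]):
            hi_ids.append((f"HI{i:03d}", status))
            i += 1
    for i, (tid, status) in enumerate(hi_ids):
        fam = h_fams[i % len(h_fams)]
        ann[tid] = _mk(tid, f"herbal indirect target {tid}", status, hi_dis[status], fam, [Location.CYTOPLASM])

    # --- compounds: round-robin partition of each group -----------------
    western_targets = [t for t, _, _ in _SHARED_TFS] + w_succ_ids + w_clin_ids + w_res_ids + w_disc_ids + w_abs_ids
    herbal_direct = [t for t, _, _ in _SHARED_TFS] + h_succ_ids + h_clin_ids + h_res_ids + h_disc_ids + h_abs_ids
    herbal_indirect = [t for t, _ in hi_ids]
    assert len(set(western_targets)) == 204
    assert len(set(herbal_direct)) == 118
    assert len(set(herbal_direct) | set(herbal_indirect)) == 862

    compounds = []
    n_w, n_h = 10, 10
    for i in range(n_w):
        links = [(t, LinkType.DIRECT) for t in western_targets[i::n_w]]
        compounds.append(
            Compound(f"WDRUG{i:02d}", f"western drug {i}", CompoundClass.WESTERN_DRUG, links)
        )
    for i in range(n_h):
        links = [(t, LinkType.DIRECT) for t in herbal_direct[i::n_h]]
        links += [(t, LinkType.INDIRECT) for t in herbal_indirect[i::n_h]]
        compounds.append(
            Compound(
                f"HERB{i:02d}", f"herbal ingredient {i}", CompoundClass.HERBAL_INGREDIENT, links
            )
        )

    # --- a small deterministic pathway collection ------------------------
    pool = sorted(ann)
    pathways = []
    for j in range(12):
        members = frozenset(pool[j * 40 : j * 40 + 60])
        category = PathwayCategory.DISEASE if j % 3 == 2 else PathwayCategory.BASIC
        pathways.append(
            PathwaySet(f"FPW{j:02d}", f"{category.value} fixture pathway {j}", category, members)
        )

    return Dataset(
        compounds=compounds,
        annotations=ann,
        pathways=pathways,
        universe_size=20_000,
    )


def load_bundled_subnetwork(name: str) -> tuple[DiseaseSubnetwork, list[Compound]]:
    """Load one of the bundled illustrative disease subnetworks
    (``apoptosis``, ``vecc`` or ``whole``), with regulator classes
    already annotated from the bundled compound table.

    These are synthetic stand-ins transcribed at topology level from the
    described signalling cascades; only the class-coverage counts they
    encode (two western targets in the apoptosis net, two herbal targets
    in the contraction net) are meaningful.
    """
    if name not in {"apoptosis", "vecc", "whole"}:
        raise CardionetError(f"unknown bundled subnetwork {name!r}")
    data = resources.files("cardionet.data")
    with resources.as_file(data.joinpath(f"synthetic_{name}_edges.tsv")) as ep, \
            resources.as_file(data.joinpath(f"synthetic_{name}_nodes.tsv")) as np_, \
            resources.as_file(data.joinpath(f"synthetic_{name}_compounds.tsv")) as cp:
        sub = assemble_subnetwork(ep, np_, name)
        compounds = read_compound_table(cp)
    return annotate_regulators(sub, compounds), compounds
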