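# Methods

## Scope and data model

The package compares two compound classes — anti-CVD western drugs and
Chinese herbal ingredients — through their protein targets.  A compound is
a set of `(target, link_type)` pairs; the direct/indirect split exists only
for herbal ingredients (herb-target databases distinguish proteins bound by
the ingredient itself from downstream-regulated ones), so western-drug
links are direct by construction and comparative statistics use the herbal
**direct** target set unless explicitly configured otherwise
(`direct_only = true`).  Target annotations carry a TTD development stage
(with `absent` as an explicit value, so census denominators are
unambiguous), a disease set, Pfam-style domain identifiers, one of seven
biochemical families, GO-derived subcellular compartments, and a TF flag
with the number of known transcriptional genes (independent of the flag:
curated TF lists contain factors with zero recorded transcriptional genes).

Identifiers are opaque accession-like strings; no cross-database ID mapping
is attempted, because mapping across drug/herb/target databases is
irreproducible without the live sources.  List-valued TSV cells use `;`,
comparisons are case-sensitive, and every printed percentage or ratio uses
half-up rounding at the printed precision (the convention that makes
`76/32 = 2.375` print as `2.38`).

## Target profiling

* **Tally**: a target group is partitioned by TTD stage; percentages are
  over the whole group including absent targets.
* **d/t** is the association count divided by the target count, per stage.
  The numerator sums each target's own disease count — a disease shared by
  two targets counts twice.  This association-count reading (rather than
  the size of the union of disease names) is the definition consistent
  with per-stage numerators such as 221 associations over 81 targets.
  d/t is reported for successful/clinical/research stages; discontinued
  targets stay in tallies but are not summarized (too few records).
* **Profiles**: domain-count bins partition targets by the length of their
  domain list; family bins partition by the seven-family enum (unannotated
  → `other`); location bins count a target once per annotated compartment,
  so location fractions may sum above 1.  Counts and fractions are both
  reported so unequal group sizes remain comparable.
* **TF enrichment** uses the same right-tail Fisher machinery as pathway
  enrichment, with an explicit background: 20,000 proteins (human proteome
  scale) of which 618 are TFs (the TRANSFAC census).  The background is a
  parameter because no canonical value exists; the qualitative conclusion
  (herbal p < 0.01, western p > 0.05) is reproduced under this documented
  default.
* **Multi-target classification** resolves each compound's direct targets
  with precedence: one target → `single_target`; all targets in one family
  → `same_family_multi`; all targets co-members of ≥ 1 pathway →
  `same_process_multi`; else `other`.  "Same biological process" is
  operationalized as pathway co-membership.

## Pathway enrichment

One-sided (over-representation) Fisher's exact test: for the 2×2 table
with `a` = targets in set ∧ pathway, the p-value is the hypergeometric
right tail `P(X ≥ a)`, accumulated from log-gamma binomial terms from the
largest support value down to `a` (summing the smaller tail terms first
limits cancellation); `a` at the lower support bound returns exactly 1.
Exactness is verified against rational enumeration (`Fraction` over
`math.comb`) to 1e-12 relative error for populations up to 40, and the
implementation is accurate far beyond that (log-gamma is exact to ~1e-14
per term).

Significance is strict `p < α` with α = 0.01.  No multiple-testing
correction is applied by default — the analysis thresholds raw p-values —
but a Benjamini–Hochberg mode is available.  The background universe is
configurable: union of pathway members (default), all annotated targets,
or an inflated explicit size.  Pathway members are intersected with the
universe before testing; results are sorted by p, ties broken by pathway
id for determinism.  The basic/disease pathway split is carried as a
category on each gene set (parsed from the GMT description token) and the
disease fraction of enriched pathways is reported.

## Networks

Target–pathway networks link `t — P` iff `t ∈ P`; compound–pathway
networks link `c — P` iff some **direct** target of `c` is in `P`.
Pathway nodes carry the enrichment p-value and significance flag as
attributes for downstream rendering; only pathways with ≥ 1 edge become
nodes (a flag restricts to significant pathways), while isolated targets
are retained.  Degree distributions are per-side frequencies; zero-degree
nodes appear as an x = 0 point but are excluded from fitting (log
undefined).

`fit_power_law` is a least-squares fit of `log f(x)` on `log x` for
`x ≥ x_min` (default 1), reporting the exponent as positive with the fit's
r².  Two modes: the default per-degree fit is exact on noiseless power-law
input; `binning="log"` aggregates frequencies into logarithmically spaced
degree bins normalized per unit degree before fitting.  The binned mode is
the estimator to use on finite samples: the sparse singleton tail of a
heavy-tailed sample flattens the per-degree fit (empirically biasing a
γ = 2.5, n = 2000 sample to ≈ 1.5), while the log-binned fit recovers
≈ 2.3–2.4 on configuration-model samples of that size.  An MLE-based
estimator would be a natural extension; the least-squares form is kept for
transparency and because only rough exponents are interpreted here.

## Disease subnetworks

A subnetwork is a node table (compartment ∈ {blood, plasma_membrane,
cytoplasm, nucleus, other}; cascade position ∈ {upstream, downstream,
unassigned}) plus a signed edge list (activation/inhibition).  Edge signs
are carried through but not interpreted — no signed-flow model is fitted.
Regulator annotation marks each node with the compound classes that
directly target it; nodes hit by both classes are "common".  The coverage
summary counts regulated nodes per class, position and compartment;
position preference is the herbal downstream fraction and western upstream
fraction among positioned regulated nodes (unassigned nodes drop out of
denominators).

The three bundled subnetworks (`src/cardionet/data/synthetic_*`) are
illustrative stand-ins: small apoptosis, vascular-endothelial-contraction
and whole-CVD cascades assembled from textbook topology, with bundled
compound tables chosen so the two countable coverage statements hold
exactly — two western-drug targets in the apoptosis net and two
herbal-ingredient targets in the contraction net.  They are labelled
synthetic in filename and docstring; no claim is made that their node sets
match any published figure beyond those counts, which is why all other
checks on this module are property-based.

## Synthetic generator

`generate_dataset` draws a two-class world whose defaults are the study
conditions the benchmarks assume:

| parameter | default | why |
|---|---|---|
| targets per class / shared | 200 / 20 | class scale between the published 118 and 204, with a shared-target overlap mirroring the common-target phenomenon |
| compounds per class | 50 | enough for per-compound enrichment without dwarfing the target pool |
| targets per compound | 1 + Poisson(2) | most compounds few-target, a tail of multi-target ones |
| herbal indirect fraction | 0.3 | herbal links are a direct/indirect mix; western all direct |
| pathways / planted / odds | 50 / 5 / 8 | a planted minority detectable at α = 0.01 |
| disease-count mean | herbal 5.0, western 2.5 | the planted d/t gap, matching the published direction and scale |
| TF fraction | 11/118, 10/204 | the published TF counts as rates |
| domain-count mean | 2.5 vs 1.5 | herbal targets are more domain-rich |
| TTD stage proportions | published census shape | categorical draw per class |
| downstream position bias | herbal 0.8, western 0.2 | the planted upstream/downstream preference |

Shared targets draw every parameter from the midpoint of the two class
settings, and the ground-truth record reports the resulting *mixture*
expectations, so recovery tests compare against the planted value actually
realized.  Planted pathways inflate the membership odds of herbal-class
targets by the configured odds ratio relative to the baseline membership
probability `size / n_targets`; non-planted pathways are class-blind.
Pathway categories cycle so one third are disease pathways.  All
randomness flows from one `numpy` `default_rng(seed)`; generation is
byte-identical per seed.

What the generator does **not** emulate: real pathway topology or overlap
structure, correlated annotations (family and location are drawn
independently given class), multi-status targets, and identifier
semantics.  Passing benchmarks therefore demonstrate statistical
correctness of the machinery under planted structure, not performance on
any real database snapshot.

`paper_fixture` is the deterministic counterpart: it realizes the
published marginal counts exactly — stage tallies 81/15/29/2 of 204 and
32/10/32/3 of 118, association totals 221/45/56 and 160/39/76, the two TF
lists with their transcriptional-gene counts and four shared TFs, and 358
of 862 all-herbal targets in TTD.  Per-target disease counts are an
arbitrary deterministic composition of the stage totals (even split,
remainder to leading targets); only marginals are meaningful.  The
published per-stage rows of the all-targets group sum to 366 while the
published in-TTD sum is 358 (the percentage 41.5% is consistent with 358);
the fixture realizes the sum and absorbs the 8-target difference into the
research-stage count (172), the one row whose percentage is not among the
reproduced cells.  Similarly the western discontinued percentage is
reproduced as arithmetic (2/204 = 1.0%), not as the internally
inconsistent printed value.

## Numerical and degenerate-input choices

* Half-up rounding via `Decimal` on the shortest string representation of
  the float, applied only at reporting time; all internal values exact.
* Empty target set, empty universe, all-zero contingency table, zero
  targets of a requested stage, and unfittable (< 3 distinct degrees)
  distributions raise errors rather than returning sentinels; dataset
  validation *reports* dangling references instead of throwing.
* An observed TF count exceeding the background TF count warns and
  inflates the background to the observed count.
* Fisher p-values are clamped to ≤ 1 after summation.
* Determinism: result lists sort by (p, id); writers emit sorted rows;
  the pipeline report is byte-stable given identical inputs and config.

## Benchmark problem sizes

Benchmarks use 10,000 null draws for calibration, 50 generator seeds for
recall/FPR, d/t-gap and position-bias recovery, 5 seeds × n = 2000 for
configuration-model exponent recovery, and 1000 random tables (N ≤ 40)
for the enumeration oracle — sizes at which every Monte-Carlo margin in
the tests is several standard errors wide while the whole suite runs in
seconds on one core.

## Known limitations

* The enrichment background ("universe") materially affects p-values and
  is not uniquely defined by the source analysis; three conventions are
  offered and results should cite the one used.
* The least-squares power-law fit, even log-binned, has finite-sample bias
  of order 0.1–0.2 at n = 2000; treat fitted exponents as descriptive.
* The bundled disease subnetworks are illustrative; conclusions about real
  cascade coverage require user-supplied curated networks.
* No multiple-testing correction by default — by design, matching the
  raw-p thresholding convention of the analysis this package reimplements.
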