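# cardionet

Comparative target-network analysis of anti-cardiovascular-disease (CVD)
**western drugs** versus **Chinese herbal ingredients**.

Western drugs and herbal ingredients act on different kinds of proteins, and
this package quantifies that difference from three target-based perspectives:

1. **Biochemical property** — for each compound class, the census of its
   protein targets against Therapeutic Target Database (TTD) development
   stages (successful / clinical trial / research / discontinued), the
   **d/t statistic** (average number of associated diseases per target,
   computed per stage as `d/t = Σᵢ |diseases(tᵢ)| / n_targets`), structure-
   domain, biochemical-family and subcellular-location distributions, and a
   transcription-factor (TF) enrichment test,
2. **Regulated pathways** — over-representation of a target set inside each
   pathway by the one-sided Fisher's exact test (right tail of the
   hypergeometric distribution, `P(X ≥ a)` for the 2×2 table of set ×
   pathway membership against a background universe, significance at
   `p < 0.01`), plus bipartite target–pathway and compound–pathway networks
   with degree-distribution / power-law analysis (`f(x) ∝ x^(−γ)`),
3. **Disease networks** — coverage of curated CVD signalling subnetworks
   (apoptosis, vascular endothelial cell contraction, whole-CVD), asking
   which class reaches which nodes and whether a class prefers upstream
   (receptor-proximal) or downstream (effector-proximal) positions.

It is written for computational pharmacologists and systems biologists who
want these comparisons as tested, reusable functions rather than one-off
database scripts.  Live database retrieval is deliberately out of scope:
the package consumes normalized TSV/GMT fixtures, ships a deterministic
fixture encoding the published census margins, and includes a synthetic
generator that plants known class differences so every stage can be
benchmarked against ground truth.

## Layout

- `src/cardionet/` — the library: `io` (TSV/GMT readers/writers and
  validation), `profiling` (tallies, d/t, distributions, TF test),
  `enrichment` (Fisher right tail, per-set and per-compound enrichment),
  `networks` (bipartite graphs, degree distributions, power-law fits),
  `disease` (subnetwork assembly and coverage), `synthetic` (generators and
  the census fixture), `pipeline` + `cli` (orchestration).
- `analysis/01…05_*.py` — narrative drivers that run each stage and write
  tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers from scratch.

## Worked example

```python
from cardionet.synthetic import paper_fixture
from cardionet.profiling import tally_ttd, dt_table, tf_enrichment
from cardionet.types import class_target_sets, round_half_up

ds = paper_fixture()
groups = class_target_sets(ds.compounds)

tally = tally_ttd(groups["western"], ds.annotations, "western")
print(tally.in_ttd_count, tally.in_ttd_pct)   # -> 127 62.3

for row in dt_table(groups["herbal_direct"], ds.annotations, "herbal"):
    print(row.ttd_status.value, row.n_targets,
          row.n_disease_associations, round_half_up(row.dt_value, 2))
# -> successful 32 160 5.0
# -> clinical_trial 10 39 3.9
# -> research 32 76 2.38

tf = tf_enrichment(groups["herbal_direct"], ds.annotations, "herbal")
print(tf.n_tf_targets, round(tf.p_value, 4))  # -> 11 0.0011
```

Reading: 127 of the 204 western-drug targets (62.3%) have a TTD record;
herbal direct targets average 5.0 associated diseases per successful-stage
target (versus 2.73 for western drugs), and 11 TFs among 118 herbal direct
targets is significant against a 20,000-protein / 618-TF background
(p ≈ 0.001 < 0.01) while 10 of 204 western targets is not (p ≈ 0.10 > 0.05).

Run the full narrative:

```bash
python analysis/01_profile_targets.py
python analysis/02_simulate_dataset.py
python analysis/03_enrichment_benchmark.py
python analysis/04_network_analysis.py
python analysis/05_disease_coverage.py
```

or the pipeline CLI: `cardionet run --config config.yaml` (subcommands
`validate`, `profile`, `enrich`, `network`, `disease`, `generate`, `run`).

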