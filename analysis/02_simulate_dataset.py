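"""Generate the synthetic benchmark dataset with planted class structure.

Draws the default two-class world (200 targets/class, 50 pathways with 5
planted at odds 8, disease-count means 5.0 vs 2.5, published TF
fractions, downstream biases 0.8/0.2) and writes the fixture files plus
the ground-truth record under results/synthetic/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from cardionet.disease import write_subnetwork
from cardionet.io import write_annotation_table, write_compound_table, write_gmt
from cardionet.synthetic import SyntheticConfig, generate_dataset, generate_subnetwork

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

config = SyntheticConfig(seed=1)
ds, truth = generate_dataset(config)
write_compound_table(ds.compounds, OUT / "compounds.tsv")
write_annotation_table(ds.annotations, OUT / "annotations.tsv")
write_gmt(ds.pathways, OUT / "pathways.gmt")
sub = generate_subnetwork(config)
write_subnetwork(sub, OUT / "subnetwork_edges.tsv", OUT / "subnetwork_nodes.tsv")
with (OUT / "ground_truth.json").open("w") as fh:
    json.dump(asdict(truth), fh, indent=2)

print(f"seed {config.seed}: {len(ds.compounds)} compounds, {len(ds.annotations)} targets, {len(ds.pathways)} pathways")
print(f"planted enriched pathways: {truth.planted_pathway_ids}")
print(f"expected class disease-count means: {truth.dt_mean}")
print(f"wrote fixture tables and ground_truth.json to {OUT}")
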