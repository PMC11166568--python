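"""Chromatin accessibility with k-mer and motif nodes.

Builds the accessibility graph (cells-peaks at weight 1.0, peak-k-mer at
0.02, peak-motif at 0.2), trains the co-embedding and asks which sequence
features sit closest to each planted motif in the shared space.
"""

import numpy as np

import cofembed as cf
from cofembed.pipelines import atac_pipeline

_, atac, seqs, _, truth = cf.simulate_multiome(
    n_types=2, cells_per_type=60, n_genes=120, markers_per_type=12, n_peaks=240, seed=2
)
pwms = {
    m["name"]: np.asarray(cf.consensus_pwm(m["consensus"]))
    for m in truth.params["motif_spec"]
}
res = atac_pipeline(
    atac, sequences=seqs, pwms=pwms,
    cfg=cf.RunConfig(scenario="atac", seed=2, n_epochs=5),
)
model = res["model"]
print("Entity types in the graph:", ", ".join(model.type_names()))

for spec in truth.params["motif_spec"]:
    name, consensus = spec["name"], spec["consensus"]
    hits = cf.query_neighbors(
        model, entity=("motif", name), k=3, type_filter=["kmer"]
    ).hits
    print(f"\n{name} (planted consensus {consensus}) nearest k-mers:")
    for _, row in hits.iterrows():
        inside = row.id in consensus or consensus in row.id
        print(f"  {row.id}  distance={row.distance:.3f}"
              + ("  <- substring of the planted site" if inside else ""))
print("\nk-mers overlapping a planted binding site co-embed with its motif.")
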