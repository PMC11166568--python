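"""Master regulators and their target genes from a joint multiome graph.

Expression and accessibility of the same cells are combined into one graph
with motif nodes; after training and softmax transformation, a TF whose
motif and gene are specific and mutually close is called a master
regulator, and genes close to both (with motif-bearing open peaks near
their TSS) are called its targets.
"""

import numpy as np

import cofembed as cf
from cofembed.pipelines import multiome_pipeline

rna, atac, seqs, ann, truth = cf.simulate_multiome(
    n_types=2, cells_per_type=80, n_genes=160, markers_per_type=15, n_peaks=320, seed=4
)
pwms = {
    m["name"]: np.asarray(cf.consensus_pwm(m["consensus"]))
    for m in truth.params["motif_spec"]
}
res = multiome_pipeline(
    rna, atac, sequences=seqs, pwms=pwms,
    cfg=cf.RunConfig(scenario="multiome", seed=4, n_epochs=5),
    include_kmers=False,
)
model = res["model"]
transformed = cf.softmax_transform(model, reference_type="cell")

gene_tab = cf.feature_specificity_table(model, "gene")
motif_tab = cf.feature_specificity_table(model, "motif")
# cutoff_quantile=0 disables the percentile specificity filter: with a
# panel of only two TFs, a median cutoff would always flag one of them
report = cf.find_master_regulators(
    transformed, [tuple(p) for p in truth.tf_pairs], motif_tab, gene_tab,
    cutoff_quantile=0.0,
)
print("Master-regulator report (gene_rank = rank of the TF gene among all genes")
print("by distance to the TF motif; small = regulator):")
print(report[["motif_id", "gene_id", "gene_rank", "filtered"]].to_string(index=False))

motif_id, tf_gene = truth.tf_pairs[0]
targets = cf.find_target_genes(transformed, (motif_id, tf_gene), ann, res["motifs"])
called = targets.loc[targets["passes"], "gene_id"].tolist()
planted = set(truth.target_genes[motif_id])
recall = len(set(called) & planted) / len(planted)
print(f"\n{motif_id}: {len(called)} target genes called, "
      f"recall of planted targets = {recall:.2f}")
print("Top calls:", ", ".join(called[:8]))
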