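"""Cross-validate the co-expression network against the chromatin gene sets,
pick the final percentile threshold per sign, and quantify knockdown effects.

The validation overlaps each (sign x expression-half) co-expression group
with the RAT gene sets at every percentile; the knockdown analysis tests
whether negatively co-expressed genes respond more strongly than positively
co-expressed ones when the vlincRNA is depleted.
"""

import pandas as pd

from vlincnet import knockdown as kd, simulate
from vlincnet.expression import spearman_full, spearman_network, stratify_by_expression
from vlincnet.pipeline import call_rat_gene_sets, preprocess_rat
from vlincnet.validation import select_final_threshold, stratified_overlap

spec = simulate.SimulationSpec(
    seed=11, n_chromosomes=2, genes_per_chromosome=25, n_vlinc=1,
    network_size_pos=5, network_size_neg=10, n_samples=32,
    vlinc_length=10_000, treatments=("DMSO",),
)
ann = simulate.make_annotation(spec)
truth = simulate.make_ground_truth(spec, ann)
expr = simulate.simulate_expression(spec, ann, truth)

halves = stratify_by_expression(expr)
net = spearman_network(expr, half_labels=halves)
processed = preprocess_rat(simulate.simulate_rat_tracks(spec, ann, truth))
gene_sets, _, _ = call_rat_gene_sets(processed, ann)

v = truth.vlincs[0]
universe = set(halves.index)
overlaps = stratified_overlap(net, v, "DMSO", gene_sets, halves, universe)
final = select_final_threshold(overlaps, net, gene_sets)
print("final threshold choice per sign:")
print(final.choices.to_string(index=False))
for sign in ("negative", "positive"):
    genes = final.genes(v, "DMSO", sign)
    print(f"validated {sign} network: {len(genes)} genes")

# knockdown: gRNA arms T (targeting) and NT (mismatch control) at days 0/3/6
tables = simulate.simulate_knockdown(spec, truth)
rho, p = spearman_full(expr)
groups = kd.group_genes(rho.loc[v], p.loc[v])
print(f"\ngene groups: {len(groups.positive)} network-positive, "
      f"{len(groups.negative)} network-negative, "
      f"{len(groups.background_positive)}/{len(groups.background_negative)} "
      "background pos/neg")

table = tables[(v, f"{v}_g1")]
expressed = kd.filter_expressed(table)
rfc = kd.relative_fold_change(table.loc[expressed])
summary = kd.effect_summary(rfc, groups, top_ns=())
print("\nknockdown effect (negative vs positive RFC), combined days 3+6:")
print(summary.to_string(index=False))
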