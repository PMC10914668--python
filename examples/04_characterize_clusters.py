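"""Characterize clusters pharmacologically and clinically.

Summarizes each cluster by its mean score on the three leading components,
maps components back to receptors through their loadings, and tabulates
cluster mean clinical effect scores.
"""

from aptaxa import (
    apply_agonism_inversion, build_affinity_matrix, build_graph,
    cluster_mean_effects, cluster_mean_scores, component_receptor_loadings,
    correlate_components_with_effects, correlation_matrix, filter_human,
    fit_ppca, floor_adjust, impute, louvain_partition, scores,
)
from aptaxa.synthetic import benchmark_dataset

data = benchmark_dataset(seed=0)
affinity = build_affinity_matrix(filter_human(data.records))
adjusted = apply_agonism_inversion(floor_adjust(affinity), data.agonism)
model = fit_ppca(adjusted.values, q=5, mask=adjusted.observed, seed=0)
completed = adjusted.completed(impute(model, adjusted.values, adjusted.observed))
partition = louvain_partition(
    build_graph(correlation_matrix(completed)), seed=0, n_restarts=100
)

drug_scores = scores(model, completed.values)
print("mean component scores per cluster (which receptor-profile directions")
print("distinguish each cluster):")
print(cluster_mean_scores(drug_scores, completed.drugs, partition, k=3).round(2))

loadings = component_receptor_loadings(model, completed.receptors, k=3)
lead = loadings["component_1"].abs().nlargest(3).index.tolist()
print(f"\nreceptors loading strongest on component 1: {', '.join(lead)}")

corr, _ = correlate_components_with_effects(
    drug_scores, completed.drugs, data.clinical, k=3
)
print("\ncomponent vs clinical-effect correlations (first 4 effects):")
print(corr.iloc[:, :4].round(2))

means, counts = cluster_mean_effects(data.clinical, partition)
print("\ncluster mean clinical scores (first 4 effects; higher = more of")
print("the side effect, or stronger efficacy for the efficacy columns):")
print(means.iloc[:, :4].round(2))
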