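"""Rank detected DNB genes by their number of high-correlation
metastasis-associated interaction neighbors — the step that singles out
a lead biomarker gene."""

import dataclasses

from dnbtip import (
    Contrast, GeneSetCollection, SimulationConfig,
    simulate_critical_transition, simulate_ppi, detect_tipping,
    deg_table, call_degs, neighbor_genes, dnb_neighbor_degs,
    metastasis_filter, correlate_gene_sets,
)

config = dataclasses.replace(SimulationConfig(seed=1), mean_shift=2.0)
series, truth = simulate_critical_transition(config)

result = detect_tipping(series)
graph = simulate_ppi(truth, n_extra_nodes=50, p_background_edge=0.02, seed=1)

nbrs = neighbor_genes(graph, sorted(result.module_genes))
contrasts = [Contrast(tp, series.timepoints[0]) for tp in series.timepoints[1:]]
deg_sets = call_degs(deg_table(series, contrasts))
tip = series.timepoints.index(result.tipping_timepoint)
pre_tipping = [c.label for c in contrasts
               if series.timepoints.index(c.numerator) <= tip]

nb_degs = dnb_neighbor_degs(nbrs, deg_sets, pre_tipping)
metastasis = GeneSetCollection(sets={"META": ("demo", sorted(truth.neighbor_genes))})
meta_nb = metastasis_filter(nb_degs, metastasis)
print(f"PPI neighbors of the DNB: {len(nbrs)}; pre-tipping DEG neighbors: "
      f"{len(nb_degs)}; metastasis-associated: {len(meta_nb)}")

edges, ranking = correlate_gene_sets(
    series, sorted(result.module_genes), sorted(meta_nb),
    r_threshold=0.8, p_threshold=0.05,
)
print("\ntop DNB genes by count of |r|>0.8 metastasis-neighbor partners:")
print(ranking.head(5).to_string())
top = ranking.index[0]
print(f"\ntop-ranked gene {top} is "
      f"{'a planted module gene' if top in truth.module_genes else 'NOT in the planted module'}")
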