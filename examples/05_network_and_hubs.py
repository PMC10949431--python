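"""Recover a planted cross-domain co-occurrence network and its hubs.

Plants a 30-node chain of conditional dependencies in the generator's
noise precision matrix, estimates the network with CLR + lasso
neighborhood selection + StARS penalty selection, and scores edge
recovery against the planted truth.  Hub classification then applies the
three filters: top-decile degree AND betweenness, core membership, and
mean relative abundance >= 0.1%.
"""

import microtempo as mt
from microtempo.io import CountTable

edges = tuple((i, i + 1) for i in range(29))
cfg = mt.SynthConfig(
    n_asvs=30, seed=1, network_edges=edges,
    seasonal_frac=0.0, season_amplitude=0.0, drift_frac=0.0, interaction_sd=0.0,
    genotype_sd=0.0, noise_sd=1.0, base_sd=1.0, reps_min=3, reps_max=3,
)
table, metadata, _, truth = mt.generate_dataset(cfg)
bacteria = CountTable(table.counts.iloc[:15], "rhizosphere", "bacteria_archaea")
fungi = CountTable(table.counts.iloc[15:], "rhizosphere", "fungi")

net = mt.estimate_network(bacteria, fungi, mt.NetworkConfig(seed=1))
est = {frozenset(e) for e in net.graph.edges}
tru = {frozenset(e) for e in truth.edges}
tp = len(est & tru)
precision, recall = tp / len(est), tp / len(tru)
f1 = 2 * precision * recall / (precision + recall)
print(f"selected lambda = {net.lambda_selected:.4f}; "
      f"{len(est)} edges ({tp} true of {len(tru)} planted)")
print(f"edge recovery: precision = {precision:.2f}, recall = {recall:.2f}, "
      f"F1 = {f1:.2f}")

occ = mt.abundance_occupancy(table, metadata)
core = mt.select_core(occ)
hubs = mt.identify_hubs(net, [bacteria, fungi], core)
print(f"hub ASVs: {len(hubs)}")
if len(hubs):
    print(hubs[["degree", "betweenness", "mean_rel_abund"]].round(4).to_string())
print("\nChain interiors have the highest betweenness, so recovered hubs sit"
      "\nmid-chain; in real data hubs flag taxa that may broker interactions.")
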