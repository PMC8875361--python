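"""Differential expression on a synthetic panel: one mutant-vs-control table.

Runs the full normalization -> dispersion -> NB Wald -> BH pipeline and
prints the most significant genes of the dsigB vs CS contrast at heat.
"""

from sigreg import diffexpr, simulate

truth = simulate.plant_truth(n_per_class=5, effect_log2=2.0, condition="heat")
config = simulate.SimulationConfig(n_genes=800, seed=3)
counts, samples, _ = simulate.simulate_counts(config, truth=truth)

tables = diffexpr.run_all_contrasts(counts, samples)
table = tables["dsigB_vs_CS_heat"].sort_values("fdr")

print(f"{len(tables)} contrast tables computed; dsigB vs CS at heat, top 6:")
print(table.head(6)[["base_mean", "log2fc", "se", "wald", "p", "fdr"]]
      .round(4).to_string())
print("-> SigB-dependent planted genes (g0000-g0009) surface with |log2fc|")
print("   near 2 and tiny FDR; unplanted genes stay near log2fc 0.")
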