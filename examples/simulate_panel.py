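"""Generate a synthetic mutant-panel count matrix and write it to TSV.

The panel mirrors the study design: control (CS) plus four sigma-factor
deletion strains, three conditions, three biological replicates — 45
samples.  Counts are negative-binomial with per-sample library-size
factors; here we also plant 5 SigB-activated genes in the heat condition.
"""

from pathlib import Path

from sigreg import io, simulate

truth = frozenset(
    simulate.PlantedRegulonEffect(simulate.gene_id(i), "B", "heat",
                                  "activated", 2.0)
    for i in range(5)
)
config = simulate.SimulationConfig(n_genes=500, seed=42)
counts, samples, sim_truth = simulate.simulate_counts(config, truth=truth)

outdir = Path("scratch/example_panel")
outdir.mkdir(parents=True, exist_ok=True)
io.write_counts(counts, outdir / "counts.tsv")
io.write_sample_table(samples, outdir / "samples.tsv")
simulate.write_truth(truth, outdir / "truth.tsv")

print(f"matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("first planted gene (g0000) mean counts by strain in heat:")
heat = samples.index[samples.condition == "heat"]
by_strain = counts.loc["g0000", heat].groupby(samples.loc[heat, "strain"]).mean()
print(by_strain.round(1).to_string())
print("-> strains lacking SigB (dsigB, dsigBCE) sit ~4-fold below CS,")
print("   because the planted effect is SigB-activated with effect_log2 = 2.")
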