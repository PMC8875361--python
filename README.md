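# sigreg

Sigma-factor regulon assignment from mutant-panel RNA-seq in the
cyanobacterium *Synechocystis* sp. PCC 6803.

Group 2 sigma (σ) factors — SigB, SigC, SigD, SigE — steer RNA polymerase to
stress-acclimation genes. A single deletion strain cannot cleanly expose a
factor's regulon, because the remaining homologues compensate. `sigreg`
implements the comparative design that can: a control strain (CS) plus four
deletion strains (ΔsigB, ΔsigD, and the triple mutants ΔsigBCE and ΔsigCDE,
which retain only SigD or only SigB respectively), profiled in three
conditions (standard growth, 1 h at 42 °C, 1 h high light at PPFD
750 µmol m⁻² s⁻¹) with three biological replicates each. A gene belongs to
the SigB regulon when it responds in *both* strains lacking SigB and in
neither strain that keeps it — and symmetrically for SigD; genes responding
only in the two triple mutants are attributed to SigC and/or SigE, which
this panel cannot distinguish.

The package is aimed at microbial transcriptomics analysts who want the
whole chain — simulation, differential expression, rule-based regulon
classification, cross-condition comparison — as a small, fully tested
Python library.

## What it computes

**Differential expression** (module `sigreg.diffexpr`). Counts K_ij are
modelled as negative binomial with mean μ_ij = s_j q_ig and variance
μ + α μ² :

* size factors s_j by median-of-ratios: s_j = median_i ( K_ij / (∏_v K_iv)^(1/m) )
  over genes with no zero count;
* per-gene dispersion α_i by method of moments pooled across replicate
  groups: α_i = max(α_floor, (σ²_pooled − μ_pooled) / μ²_pooled) on
  normalized counts;
* for each contrast (mutant vs CS within a condition, plus stressed CS vs
  standard CS), group means on the common scale are estimated from
  normalized counts, giving log₂FC = log₂(q̂_test / q̂_ref), a standard
  error from the NB variance model, the Wald statistic W = log₂FC / SE and
  a two-sided normal p-value;
* Benjamini–Hochberg FDR within each contrast table.

There is deliberately no dispersion or fold-change shrinkage, no
independent filtering and no outlier refitting: every step has a
closed-form or brute-force oracle in the test suite.

**Regulon assignment** (module `sigreg.regulon`). Per condition, each gene
gets an UP/DOWN/NS call per mutant (FDR < 0.05), enters classification if
significantly ≥ two-fold regulated (|log₂FC| ≥ 1) in at least one mutant,
and is labelled from its four-strain pattern: SigB, SigD, SigCorE, shared,
or none — with the published tolerance for opposite-direction changes in
the complementary triple mutant. Deleted σ-factor genes are masked in their
own deletion strains. Regulons are compared across conditions and annotated
with the control strain's own stress response.

**Synthetic data** (module `sigreg.simulate`). A seeded NB count generator
for the full 45-sample design with per-sample library-size factors and
planted, condition-specific regulon effects, so that the whole pipeline is
testable end to end with known ground truth.

**Reporters** (module `sigreg.reporters`). Luciferase promoter activity
(luminescence / OD₇₃₀) with fold induction, and dilution-corrected growth
curves with log-linear growth rates.

## Worked example

`examples/regulon_assignment.py` plants 20 genes per regulon class
(SigB/SigD/SigC-or-E, up and down, four-fold effects) among 1000 genes,
runs the full pipeline and scores recovery:

```
regulon sizes at heat:
label
SigB       41
SigCorE    40
SigD       39
shared      1

recovery per planted class:
condition      metric        class  value  n
     heat sensitivity    SigB_down   1.00 20
     heat sensitivity      SigB_up   1.00 20
     heat sensitivity SigCorE_down   1.00 20
     heat sensitivity   SigCorE_up   1.00 20
     heat sensitivity    SigD_down   1.00 20
     heat sensitivity      SigD_up   0.95 20

overall sensitivity 99.17%, false assignment rate 0.035%
```

Each 40-gene class (20 up + 20 down) is recovered almost completely — the
41st SigB gene and the single "shared" gene are borderline cases pulled in
by noise — and essentially no unplanted gene is assigned to a regulon. The
other scripts in `examples/` cover the simulator, a single
differential-expression table, cross-condition regulon overlap, and the
reporter/growth utilities; each prints a short interpretation of its
numbers.

The same pipeline runs from the shell:

```sh
sigreg simulate --n-genes 3000 --seed 1 --out run/sim
sigreg analyze --counts run/sim/counts.tsv --samples run/sim/samples.tsv --out run/out
sigreg evaluate --truth run/sim/truth.tsv --analysis run/out
sigreg report --analysis run/out
```

All inputs and outputs are plain TSV; an editable rRNA-operon exclusion
list template ships in `examples/data/`.

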