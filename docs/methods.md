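# Methods

## The inference problem

Group 2 σ factors of *Synechocystis* sp. PCC 6803 (SigB, SigC, SigD, SigE)
are partially redundant regulators. The panel analysed here identifies the
SigB and SigD regulons by *co-occurrence* of expression changes across four
deletion strains rather than by any single knockout: ΔsigB and ΔsigBCE are
the only two strains lacking SigB, ΔsigD and ΔsigCDE the only two lacking
SigD, and the two triple mutants are the only strains lacking SigC and
SigE. A SigB-dependent gene must therefore respond in ΔsigB *and* ΔsigBCE
but not in ΔsigD; a response confined to the two triple mutants points to
SigC and/or SigE, which this design cannot separate. Each strain is
profiled in three conditions (standard; 1 h at 42 °C; 1 h at PPFD
750 µmol m⁻² s⁻¹) with three biological replicates — 45 samples.

## Count model and differential expression

Counts are modelled as negative binomial in the mean/dispersion
parameterisation, Var(K) = μ + α μ², with per-sample size factors entering
the mean multiplicatively. This single parameterisation is shared by the
simulator and the test stage.

**Normalization.** Median-of-ratios: for sample j,
s_j = median over reference genes i of K_ij / geomean_i, where the
reference set is the genes with no zero count. The plain median of ratios
is used (not the exponentiated median of log ratios); the two agree
whenever the reference set has odd size. There is no pseudo-reference
fallback: a matrix without any zero-free gene is rejected, which for this
organism's compact transcriptome (~3,600 genes) does not occur in
practice.

**Dispersion.** Per gene, method of moments on normalized counts, pooled
across all replicate groups: α_i = max(α_floor, (v_i − m_i) / m_i²), with
v_i the df-weighted pooled within-group sample variance, m_i the grand
mean, and α_floor = 1e-8 for numerical stability at the Poisson limit.
With the full design this gives 30 residual degrees of freedom per gene.
No shrinkage toward a mean–dispersion trend is applied — by design, so the
estimator stays a two-line formula with a Monte-Carlo oracle.

**Group means and the Wald test.** For a contrast (test group, reference
group), each group's mean on the common scale is estimated as the average
of size-factor-normalized counts, q̂ = (1/n) Σ_j K_j / s_j. This solves the
unbiased estimating equation Σ_j (K_j/s_j − q) = 0 and *coincides with the
NB maximum-likelihood fit with log(s_j) offsets whenever the size factors
within the group are equal*. It was chosen over the general-offset MLE for
one property the MLE lacks: the fitted fold change depends on the data
only through normalized counts, so rescaling any sample together with its
size factor leaves every log₂FC unchanged to machine precision — an exact,
testable statement of offset correctness. The efficiency loss relative to
the MLE is negligible for the size-factor range this design produces
(0.7–1.4).

The standard error comes from the NB variance model by the delta method,
Var(log q̂) = n⁻² Σ_j (1/(q̂ s_j) + α), which again equals the
information-based variance of the NB fit for equal within-group size
factors. Then W = log₂FC / SE is referred to a standard normal, two-sided.
Genes with zero counts in both groups are flagged `untestable` (log₂FC 0,
p 1) and excluded from FDR adjustment; a single all-zero group is given a
half-count pseudo-mean (0.5 / Σ s_j, the usual continuity correction) and
the log₂FC is capped at ±10.

**Multiplicity.** Benjamini–Hochberg step-up within each contrast table
separately, matching per-contrast gene lists.

**Calibration.** On truth-free simulations at the study design (α = 0.1,
baseline median 200), the realised per-contrast type-I error at p < 0.05
is ≈ 6.1% rather than 5%: the plug-in of a 30-df moment estimate of α into
the Wald SE, plus the n = 3 normal approximation, are each mildly
anti-conservative, and neither is corrected (no t-reference, no dispersion
shrinkage — both would trade documentability for calibration). After BH
adjustment the null yields essentially no calls (≈ 0.03% of genes at
FDR < 0.05). The acceptance suite checks both rates on simulated panels.

## Regulon rules

Per condition and mutant strain, a gene's status is UP (DOWN) when
FDR < 0.05 and log₂FC is positive (negative), else NS. A gene enters
classification when it is significantly at-least-two-fold regulated
(|log₂FC| ≥ 1 *and* FDR < 0.05) in at least one mutant; inside the rules,
sub-two-fold but significant changes still count as regulated. The two-fold
gate deliberately includes the significance condition so that large but
noisy fold changes cannot seed regulons.

With the status pattern (ΔsigB, ΔsigD, ΔsigBCE, ΔsigCDE):

| label | rule |
|---|---|
| SigB down | DOWN, NS, DOWN, {NS or UP} |
| SigB up | UP, NS, UP, {NS or DOWN} |
| SigD down | NS, DOWN, {NS or UP}, DOWN |
| SigD up | NS, UP, {NS or DOWN}, UP |
| SigCorE | both triples same direction, both singles NS |
| shared | any other pattern with ≥ 2 regulated strains |
| none | everything else |

"Not in the other strains" is read strictly as NS in the other single
mutant; an opposite-direction change is tolerated exactly in the
complementary triple mutant and nowhere else. The five labels partition
the candidate set, the rules are mutually exclusive by construction, and
swapping the roles B↔D (and BCE↔CDE) maps SigB assignments onto SigD
assignments — both properties are enforced by exhaustive enumeration over
all 3⁴ = 81 patterns against an independently written transliteration of
the rules.

Each deleted σ-factor's own gene is masked (status undefined) in its
deletion strains; the default locus tags are sigB = sll0306,
sigC = sll0184, sigD = sll2012, sigE = sll1689, overridable per run. A
candidate gene whose rule pattern touches a masked status is flagged
`unclassifiable` rather than silently dropped.

Cross-condition comparison emits, per label, the gene sets per condition,
their intersection and each condition's private genes. Regulon genes are
additionally annotated with the control strain's own stress response
(stressed CS vs standard CS, significance/sign rule only — no fold-change
gate), mirroring how published regulon diagrams mark stress-induced genes.

## Synthetic data

The generator emulates exactly the features the analysis consumes:

* per-gene baseline means from a log-normal law, median 200, ln-scale
  sd 1.0 — a moderate spread keeping the central 95% of genes between
  ≈ 28 and ≈ 1400 expected counts, typical of a well-sequenced bacterial
  RNA-seq library without an extreme low-expression tail;
* a shared NB dispersion (default α = 0.05; the null-calibration studies
  use 0.1);
* per-sample size factors uniform on [0.7, 1.4];
* planted effects that encode the σ-dependency structure: an *activated*
  target's mean is multiplied by 2^(−effect_log2) in every strain lacking
  the governing factor (a *repressed* target by 2^(+effect_log2)); "CorE"
  effects fire only when both SigC and SigE are absent. The control strain
  is never affected. Default planted effect size is effect_log2 = 2
  (four-fold) — no effect-size or dispersion estimates exist for the real
  panel, so these are generator choices, not measured values.

One integer seed determines the output bit for bit, on disk included.

What the generator does **not** emulate: GC or length bias, batch effects,
correlated genes (operons!), count outliers, library-size extremes, or any
mean–dispersion trend. Passing recovery tests therefore demonstrate the
pipeline's logic under its own model assumptions, not performance on real
sequencing data, where shrinkage-based tools remain preferable.

## Reporters and growth

Promoter activity is luminescence / OD₇₃₀ (OD must be positive); fold
induction is the stress/standard activity ratio, with optional subtraction
of an empty-vector background from both terms (off by default — the
control strain's background is negligible). Growth records attach each
dilution factor to the measurement taken immediately after it; the
corrected OD at time t is the measured OD times the product of all
dilution factors applied at or before t, and growth rates are OLS slopes
of ln(corrected OD) versus time (day⁻¹), requiring ≥ 3 points in the
fitting window.

## Numerical and design choices

* TSV everywhere (tab separator, UTF-8, '.' decimal, header cell
  `gene_id`): the matrices are small and byte-exact round-trips are
  testable. Gene identifiers are opaque strings.
* FDR is computed by the statsmodels BH implementation behind the
  `bh_adjust` surface; tests compare it against an O(m²) brute-force
  step-up.
* Exclusion lists (e.g. the rRNA operons) are user-editable files; genes
  absent from the matrix are warnings, an exclusion that would empty the
  matrix is an error.
* Thresholds (FDR 0.05, |log₂FC| gate 1) are configuration values with the
  published defaults.
* Problem sizes in the test and acceptance runs (2000-gene null panels,
  3000-gene recovery panels) keep each run in the seconds range while
  holding per-rate Monte-Carlo error near 0.5%.

## Known limitations

* The simplified DE stage is mildly anti-conservative at n = 3 (see
  Calibration) and will not reproduce a specific DESeq2 version's marginal
  calls; regulon membership of borderline genes can differ accordingly.
* SigC and SigE regulons are not separable from this strain panel, by
  construction.
* The two-group model has no replicate or batch covariates.
* Reported wet-lab quantities (fold inductions, growth differences) are
  reproducible only as arithmetic; their values depend on measurements no
  simulator can supply.
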