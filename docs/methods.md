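# Methods

## The measurement and the model

The package analyzes clonal erythroid colonies (BFU-E) grown from CRISPR-
edited human HSPCs. Each colony derives from a single progenitor, so its
genotype is a fixed combination of per-allele editing outcomes, and its
globin transcript mix is one realization of the genotype-phenotype map
for fetal hemoglobin (HbF) silencing. The pipeline has four analysis
stages plus a generator:

1. **Genotyping** — per-allele edit calls are collapsed into ordinal
   dosage variables: disrupted HBG1/2 promoter alleles (0–4, the two
   homologous promoters pooled because their edits behave
   exchangeably), a BCL11A allelic series (0 wild type, 1 heterozygous
   exon-2 frameshift, 2 heterozygous exon-4 frameshift — coded above the
   exon-2 heterozygote because the truncated exon-4 product acts as a
   dominant negative — 3 biallelic frameshift), ZBTB7A frameshift count
   (0–2), and deletion dosages (0–2) for the paired-guide structural
   variants spanning HBB–HBD, the 3.5 kb region upstream of HBD, and
   their union.
2. **Quantification** — delta-Ct expression of HBG1/2 and HBB relative
   to the HBA1/2 endogenous control, the γ-fraction of β-like mRNA
   100·HBG/(HBG+HBB), and the HBG1:HBG2 split from G:A Sanger peak
   ratios.
3. **Interaction mixed models** — for response y (per-colony expression
   measure),

       y = Xβ + Zμ + ε,

   X holding an intercept, the dosage mains and their pairwise products,
   and Z random-intercept indicators for cell donor and for the gRNA set
   delivered to each culture condition (the unedited control condition
   is the reference level and carries no indicator). Inference on β uses
   t statistics with Satterthwaite degrees of freedom; the interaction
   coefficients are the quantities of scientific interest (synergy or
   antagonism between cis elements and trans factors).
4. **Chromatin quantification** — CAPTURE interaction calls filtered at
   BF ≥ 20 (inclusive) and normalized to relative interaction frequency
   per kb, rif = count·10⁶/(bait bp · total filtered count); 3C qPCR
   ligation products normalized to a TUBA1A control interaction and
   summarized as mean ± SEM over biological replicates.

## REML estimation

Variance components are estimated by restricted maximum likelihood.
With variance ratios γ_g = σ_g²/σ_e² and W = I + Σ_g γ_g Z_g Z_gᵀ, the
residual variance is profiled out analytically and the criterion

    (n−p)·log(yᵀP̃y) + log|W| + log|XᵀW⁻¹X|

is minimized over log γ by Nelder–Mead from a fixed pair of starts
(γ = 0.1 and 1.0 for all components), making the fit deterministic.
All W⁻¹ products use the Woodbury identity through a Cholesky factor of
I_q + Γ^{1/2}ZᵀZΓ^{1/2}, which stays stable as any γ → 0, so each
evaluation costs O(nq²) for q random-intercept levels. Ratios driven
below 10⁻⁸ are profiled exactly at the zero boundary and reported as
boundary estimates rather than errors; log-ratios are clipped at ±30 so
an unidentifiable component (e.g. a random factor collinear with the
intercept) cannot overflow. Fixed effects are then generalized least
squares at the fitted components.

Numerical checks built into the test suite: on a balanced one-way
design the components reproduce the ANOVA method-of-moments closed
forms to better than 10⁻⁶, and the whole fit matches statsmodels
`MixedLM` (an independent implementation) on single-factor designs.

## Satterthwaite degrees of freedom

For a contrast c, the test statistic is t = cᵀβ̂ / √(cᵀCc) with
C = (XᵀV̂⁻¹X)⁻¹ and

    df = 2·(cᵀCc)² / (gᵀA g),

where g is the gradient of cᵀCc in the variance components
(∂C/∂σ_j² = C XᵀV⁻¹(∂V/∂σ_j²)V⁻¹X C) and A is the inverse expected REML
information, I_jk = ½·tr(P Ġ_j P Ġ_k), over the components not at the
zero boundary. Two exact limits anchor the approximation: with no
random components df = n − p exactly, and for the grand mean of a
balanced one-way design df = k − 1. If the information matrix is
singular the code falls back to the residual df with a warning.

Confidence bands for interaction profiles (predicted means over a
dosage grid) use the same machinery per grid point; lines across the
second factor are exactly parallel iff the interaction coefficient is
zero.

Known limitation — calibration with few random-effect levels.  When a
random factor has only a handful of levels and the fixed effects are
partially confounded with it (each partial deletion delivered in its
own gRNA condition, so the interaction product is nonzero only in the
combined condition), the Satterthwaite interaction test runs mildly
anticonservative at 120-colony cohorts: true level ~0.055–0.07 in our
simulations, and R's lmerTest produces the same level on identical
datasets (p-value correlation 0.99), so this is the REML-plug-in
small-sample behavior of the method itself, not of this
implementation.  Likewise, 95% intervals undercover slightly (~92–93%)
with only three donors and recover the nominal level with six.  The
Kenward–Roger correction that addresses this regime is deliberately
out of scope.  Consequences for the built-in studies: the type-I
calibration study uses a design in the method's calibrated regime —
one combined-delivery condition whose colonies span the full dosage
grid, with donor random intercepts (measured level ~0.052) — and the
recovery/coverage study uses six donors, matching the larger colony
panels (n = 6 biologically independent experiments).  Interaction
p-values from heavily condition-confounded designs should be read with
this mild anticonservativeness in mind.

## The synthetic colony generator

The generator emulates the study design, not sequence-level Cas9
biology: alleles at each targeted locus are edited independently with a
per-guide probability (default 0.7, a typical RNP editing rate in
HSPCs), edited alleles draw a signed indel length from a configurable
spectrum concentrated on the −13 bp element deletion plus small indels,
and paired-guide loci draw deletion/inversion outcomes per allele
(defaults 0.45/0.10). Promoter disruption truth follows the same
">2 bp inside the 13 bp element" rule the caller applies; coding-locus
frameshift truth is "net indel length not divisible by 3". Junction-
qPCR presence tables are derived deterministically from the allele
states under the convention that an inverted segment still amplifies
the internal amplicon. A configurable fraction of promoter-guide
colonies acquires a whole-region structural variant and is flagged for
exclusion, as are colonies with unphaseable heterozygous BCL11A exon-2
plus exon-4 edits.

Expression is generated directly from the mixed model on the γ-fraction
scale: baseline 0.20 (the unedited ~20% HBG regime), per-dosage effects
of 0.05–0.16 chosen to span the observed induction range up to the
70–80% fraction seen with strong combined perturbations, donor and
guide-condition intercept SDs of 0.03, residual SD 0.08, and identity
response scale with clipping to [0,1] (log scale available). Under the
defaults ~0.5% of colonies clip at 0; clipped colonies yield
undetermined Cts (no amplification) in the synthesized plates. Ct
synthesis inverts the delta-Ct formula exactly around a fixed reference
Ct of 20, so quantification round-trips to the generated ratios at
1e−9.

What the generator does *not* model — and hence what passing tests do
not establish about real data: zygosity coupling between alleles of one
cell, sequence-dependent repair-outcome spectra, clonal mosaicism
within a colony, amplification-efficiency differences between targets,
Sanger trace noise beyond two-peak ratios, and genomic distance decay
in chromatin contact profiles. Tests demonstrate the estimators are
correct under the stated model, not that the model captures every
feature of BFU-E data.

## Problem sizes and determinism

All Monte-Carlo studies are seeded and deterministic. The acceptance
suite uses: a 6×10 balanced design for the closed-form oracle; 1000
replicates of 120 colonies (one combined-delivery condition, 6 donors)
for type-I calibration of the interaction test (binomial tolerance
±0.015 around 0.05); 200 replicates of 500 colonies (4 conditions ×
125, 6 donors) for interaction recovery and CI coverage; ~10,000
colonies for the genotyping round-trip; and 50,000-read multinomial
profiles for the chromatin checks. These sizes give Monte-Carlo errors comfortably below
the assertion tolerances while keeping the full suite to a few minutes.

## Design choices on genuinely open points

- **Response scale**: identity on the γ-fraction by default; the printed
  model coefficients in colony studies are rarely accompanied by an
  explicit scale, so both identity and log transforms are exposed and
  the choice is a `ModelSpec` field.
- **qPCR efficiency**: 2.0 (perfect doubling) for both globin and 3C
  normalization, configurable per call; technical replicate Cts are
  averaged before delta-Ct.
- **Substitutions count toward the >2 bp rule** equally with indels: the
  rule is stated in bases mutated, not in indel length.
- **BF filtering precedes normalization**: quantitative chromatin
  analysis is defined on significant interactions only, so the filtered
  total is the denominator; profiles then conserve exactly.
- **Multiplexed baits** are measured as the union of their sgRNA anchor
  windows, so overlapping anchors are not double counted.
- **Unphaseable BCL11A genotypes** (het exon-2 + het exon-4) are
  excluded from the allelic series rather than guessed, because the
  series has no defined rank for them.
- **No multiplicity correction** across the three model variants; raw
  per-coefficient p-values are reported.
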