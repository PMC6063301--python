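# Methods

This note documents the models, parameter choices and numerical conventions
behind altiscan, and what the synthetic-data experiments do and do not
demonstrate.

## Data model and conventions

Genotypes are diploid dosages of `allele_b` in {0, 1, 2} with −1 for
missing, stored as samples × variants `int8`. Coordinates are 1-based
inclusive; chromosome labels carry no `chr` prefix. Derived-allele
polarization comes from an explicit annotation (`ancestral ∈ {a, b,
unknown}`); variants with unknown ancestry are excluded from polarized
frequencies. All per-SNP significance statistics (Spearman, mixed model,
PBS, Fisher) are two-sided or orientation-free, so an unpolarized panel
yields identical p-values with orientation-dependent signs of ρ and β; the
scan model falls back to allele-b orientation with a warning when no
annotation exists.

## Quality control

The QC chain runs in a fixed order so removal counts are reproducible:
variant call rate ≥ 99% → sample missingness ≤ 10% → Hardy–Weinberg exact
p ≥ 10⁻⁷ (recomputed on retained samples) → optional MAF. The HWE test is
the exact conditional (Levene/Haldane) test summing probabilities of
heterozygote counts no more likely than observed — the PLINK convention,
no mid-p. Relatedness uses method-of-moments IBD from identity-by-state
counts against HWE expectations at sample allele frequencies
(PI_HAT = P(IBD=1)/2 + P(IBD=2), truncated into [0, 1]); the removal tool
drops the higher-missingness member of each pair with PI_HAT > 0.35. LD
pruning is greedy and windowed (50 SNPs, step 5): while any retained pair
in a window exceeds r², drop the lower-call-rate member (tie → later map
position). At merge, A/T and C/G SNPs are always dropped (strand
ambiguity) and REF/ALT swaps are recoded g → 2 − g; this is the
conservative standard where the array protocols are unknown.

## Selection statistics

**Spearman scan.** Midrank correlation of per-population derived frequency
vs altitude; two-sided p by the t approximation with n−2 df. The
approximation is documented as coarse for < 10 populations; an exact
permutation mode (feasible to n = 8) exists for small panels and agrees
with the t approximation within a factor of ~2 there. Variants with
constant frequency or < 4 populations do not enter the test count.
Per-population frequencies are unweighted by sample size.

**Mixed model.** Phenotype is each sample's population altitude in metres
(p-values are scale-invariant). The null y = μ + u + ε with
u ~ N(0, σ²g K) is fitted by REML over δ = σ²e/σ²g on the kinship
eigenbasis: a 41-point grid on log δ ∈ [−10, 10] followed by bounded
scalar refinement. K is the standardized-genotype covariance Z Zᵀ/m with
mean imputation of missing calls (keeps the eigenstructure usable without
dropping samples) and monomorphic variants excluded. Per-SNP tests keep
the null variance components and run weighted least squares in the
eigenbasis (the defining EMMAX shortcut — orders of magnitude faster than
per-SNP REML); the Wald test uses the per-variant residual variance in the
whitened space with n−2 df, which makes the identity-kinship limit agree
with ordinary least squares exactly. With a phenotype that is constant
within populations the heritability ratio estimates ≈ 1 and δ sits at the
grid floor; that boundary is expected, not a failure — heritability is
only weakly identified when the GRM spectrum is flat outside the structure
spikes. Calibration, not power, is the method's contract: on the null
study profile the genomic inflation λ_GC is ~1.0 where naive regression
gives ~3–4. The power cost is real: a frequency shift of 0.15 per km
yields ~25% power at 5×10⁻⁸ at the default profile; ~0.25 per km is the
regime where the mixed model itself reaches genome-wide significance for
most planted loci.

**FST and PBS.** Per-SNP Weir & Cockerham (1984) two-population estimator
from genotype counts with observed heterozygosity (no HWE assumption);
undefined (not 0) when both populations are monomorphic; negative
estimates are preserved for averaging and clamped to 0 only inside the PBS
log transform (FST is also capped at 1 − 10⁻¹²). Multi-locus FST is the
ratio of summed variance components. PBS is computed per SNP, focal group
H pooled from populations at ≥ 2,500 m, against a closest lowland
reference C and an outgroup O; the empirical threshold is the k-th largest
finite value with k = ⌈N(1 − percentile/100)⌉ and ties are kept, so a
99.99th-percentile scan of 20,000 variants flags exactly the top 2 absent
ties.

**Evidence combination.** PBS rank-p uses rank/N with mean-rank ties.
Fisher's χ² = −2 Σ ln p with 2k df combines the Spearman, mixed-model and
PBS-rank p-values for variants where all three exist (N counts only
those); p = 0 is clamped to 10⁻³⁰⁰ with a warning. The three tests are
not independent, and no dependence correction is applied — the combined p
ranks evidence rather than calibrating family-wise error; the strict
Bonferroni cut 0.01/N controls the candidate list size. Candidate regions
chain significant SNPs within 500 kb (single linkage). The clustering
distance is a configuration knob chosen to produce megabase-scale clusters
with internal gaps; the scan model reports single-SNP clusters as
singleton regions (min_snps = 1) because an isolated causal SNP is a
legitimate candidate, while the standalone clustering operation defaults
to min_snps = 2.

## Demography

**ROH.** PLINK-style: 50-SNP windows are homozygous when they carry 0
heterozygous and ≤ 5 missing calls; SNPs with ≥ 5% homozygous overlapping
windows are eligible; maximal eligible runs, broken at heterozygous calls
and capped at 5 missing calls per segment, are reported when ≥ 100 SNPs.
Segment bounds use SNP positions, not padded window edges. The window size
(50) is the PLINK default, exposed as a parameter. Inputs should be
MAF-filtered (> 0.05) and LD-pruned (r² ≤ 0.5). Recovered boundaries of a
planted segment trail the truth by up to one window — inherent to the
window-fraction rule.

**Inbreeding.** F = (O_hom − E_hom)/(N − E_hom) with per-variant expected
homozygosity 1 − 2p(1−p) summed over the sample's non-missing polymorphic
variants; no small-sample correction (difference O(1/n)).

**Ne from LD.** Pairs of intra-chromosomal variants are binned by
recombination distance c (Morgans, from cM annotation, a map file, or a
constant 1 cM/Mb fallback); each bin's mean r² is adjusted by −1/n with
n = 2 × samples (the "r² − 1/n" sample-size adjustment). Nonlinear least
squares fits y = 1/(α + βc) (positivity bounds, linearized 1/y start);
long-term Ne = β/4, per-bin Ne_t = (1/y − α̂)/(4c) at t = 1/(2c)
generations, harmonic mean across bins, 29 years per generation. On
noiseless generated bins the recovery is exact to optimizer tolerance.
Only populations with ≥ 10 samples are accepted (harmonic means are
sample-size sensitive). The founder-mosaic simulator provides the
generative check: a pool of K founder haplotypes copied with switch rate
1/Morgan behaves like a haploid population of size K over modest c, so the
fitted Ne tracks K/2 (within ~25% per panel, closer after averaging
replicates) and orders correctly between pool sizes — bins must span
enough recombination distance (up to ~0.3 M) for the decay to be visible.

**Divergence time.** t = −2·Ne·ln(1 − F_ST) generations (≈ 2·Ne·F_ST for
small F_ST), the pure-drift clean-split relation, labelled approximate and
downward-biased under migration. The generative check simulates two
populations drifted with F = 1 − e^(−T/2Ne) and recovers T within a few
percent at 20,000 loci.

**f3 / D.** Frequency-based estimators (inputs are diploid panels;
pseudo-haploid sampling of damaged ancient reads is out of scope).
Admixture f3(C; A, B) subtracts the target's heterozygosity bias
c(1−c)/(2n_c − 1) per SNP; outgroup f3 applies no correction and warns
when the "outgroup" correlates > 0.9 with X. D uses the frequency form
Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz). Standard errors come from a weighted
delete-one block jackknife (Busing et al. 1999 variance formula) over
contiguous 500-SNP blocks in genome order (last block short); for two
equal blocks the SE reduces to |a−b|/2 exactly. Conventional gates:
populations need ≥ 6 samples; D is significant at |Z| ≥ 4; f3 indicates
admixture at Z ≤ −3. The Mantel test permutes rows/columns of one matrix
jointly with a two-sided +1-corrected p; when n! fits the permutation
budget the enumeration is exact and deterministic.

## The synthetic-data generator

`SimConfig` defaults define the study profile: 20 populations of 10–20
samples, drift F per population uniform on [0.01, 0.2], altitudes uniform
on 100–4,500 m, 20,000 variants evenly spaced (5 kb, 1 cM/Mb) on 4
chromosomes, ancestral derived frequencies uniform on [0.05, 0.95], 0.5%
of loci altitude-selected with slope 0.15 per km, plus two external
altitude-0 reference panels (EXC ~ East-Asian-like close reference, F
0.02; EXO ~ European-like outgroup, F 0.05; 30 samples each). Population
frequencies follow the Balding–Nichols model
(Beta(p(1−F)/F, (1−p)(1−F)/F)); genotypes are Binomial(2, p_k).

Selection is planted at the population-frequency level — the scan
statistics see only frequencies, so this is the minimal sufficient
mechanism — by shifting p_k to clip(p_k + s·altitude_km, 0.01, 0.99) and
redrawing genotypes at the chosen loci only (everything else is
bit-exact). Selected loci are drawn from standing variation with ancestral
derived frequency in [0.05, 0.3]: an additive shift saturates at the
clamp for high-frequency alleles and cannot express an altitude cline,
and a rising adaptive allele starting from low/moderate frequency is the
biologically standard picture. In that regime the planted monotone signal
gives Spearman ρ > 0.7 at ≥ 90% of loci over 20 populations.

What the generator does **not** emulate: linkage between selected and
neighbouring variants (selection is planted at isolated SNPs, so no
haplotype sweep signature), array ascertainment bias, genotyping error,
recombination hotspots, and admixture-graph history beyond simple
frequency mixtures. Passing tests therefore demonstrate the statistics'
contracts — calibration, threshold semantics, parameter recovery under the
assumed models — not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- HWE: log-gamma enumeration, p_obs comparison with a 1 + 10⁻¹² guard
  against float ties; monomorphic sites return p = 1.
- r²: pairwise-complete samples; undefined below 2 complete pairs or at
  zero variance (flagged NaN, never 0).
- Kinship/GRM: eigenvalues clamped at ≥ 0 before REML.
- PBS threshold and rank-p are order statistics, deterministic under ties.
- Region clustering ties for the top SNP break to the smaller position.
- Every generator takes a seed; identical config + seed reproduce
  bit-identical panels, and the scan itself is deterministic given the
  panel.

## Problem sizes used in tests and the acceptance script

Calibration and recovery experiments run at the default study profile
(20 populations, 20,000 variants, ~330 samples), with 3–5 replicates for
the recovery rates, 50 replicates of 5,000-SNP panels for the D-statistic
null, and 1,500–2,000-variant mosaics for the Ne checks. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
a full run in the tens of seconds.

## Known limitations

- The EMMAX shortcut understates per-SNP uncertainty when a single variant
  explains much phenotypic variance (variance components are not refitted).
- The divergence-time relation ignores migration and post-split Ne change;
  its output is an isolation-scale indicator, not a date.
- The LD-Ne trajectory inherits the linear-growth assumption of the
  underlying regression; t = 1/(2c) is an approximate timescale mapping.
- ROH detection parameters are tuned for array-density data; they are not
  appropriate for sequencing data without re-tuning.
- The Spearman scan treats populations as exchangeable observations;
  shared ancestry among populations is only handled by the mixed model and
  PBS, not by the rank correlation.
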