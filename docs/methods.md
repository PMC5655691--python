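# Methods

`popstrat` compares two closely related livestock populations genotyped on a
shared medium-density SNP panel.  The motivating setting is a pair of
national dairy-cattle evaluations (by convention labelled PL and DE
throughout) whose bulls carry deregressed breeding values for production
traits and somatic cell score, but the code is agnostic to species and
trait.  This note records the models, the defaults, and the choices made
where the design was genuinely open.

## Quality control and marker intersection

Each population is screened independently: a SNP is kept when its minor
allele frequency (counted-allele frequency folded to ≤ 0.5, computed on
non-missing calls) is ≥ `maf_min` (default 0.01) and its call rate is
≥ `callrate_min` (default 0.90); both thresholds are inclusive.  Only
markers surviving QC in both populations are carried forward, in a single
shared order, with the counted allele harmonised from the panels' allele
labels (a swapped labelling sign-flips the genotype column; an
irreconcilable one drops the SNP with a warning).  Screening per population
*before* intersecting follows the natural reading of a two-stage protocol
("filter, then intersect"); the alternative order changes only which SNPs
fail MAF marginally.

Missing genotypes are excluded from the MAF denominator.  Downstream, in
the SNP-BLUP design matrix, a missing call is set to 0 — the heterozygote
code, which is also the column mean of the symmetric −1/0/+1 coding.  This
is a pragmatic fill for the low missingness the QC admits (≤ 10%, typically
≪ 1%), not an imputation.

## Linkage disequilibrium

For two loci with counted-allele frequencies p₁, p₂ and AB-haplotype
frequency p_AB, LD is the squared allelic correlation
r² = D²/(p₁(1−p₁)p₂(1−p₂)) with D = p_AB − p₁p₂, which on phased 0/1
columns equals the squared Pearson correlation of the allele indicators
(computed that way, in bulk, per chromosome).  Monomorphic loci have no
defined r² and their pairs are excluded.  When only unphased genotypes are
available, the two-locus haplotype frequencies come from an EM iteration
that redistributes the double heterozygotes between coupling and repulsion
phase each round; all other genotype classes resolve unambiguously.

Same-chromosome pairs up to 5 Mbp apart are grouped into nine fixed
intervals (Mbp): [0–0.025), [0.025–0.05), [0.05–0.075), [0.075–0.12),
[0.12–0.2), [0.2–0.5), [0.5–1.5), [1.5–3), [3–5] — all half-open except the
last, which is closed.  The per-interval mean r̄²ᵢ is regressed by OLS on
1/√dᵢ with dᵢ the interval's **upper boundary** (taken literally; not the
midpoint), giving the decay fit r²(d) = α + β/√d.  Because the predicted
decrease between any two distances is β(1/√d₁ − 1/√d₂), the ratio of two
populations' decreases over a common distance pair equals β_A/β_B.

Between-population differences per interval use a paired t-test on per-pair
r² differences (pairs matched on the ordered SNP-id pair), one-sample on
the differences with n−1 degrees of freedom, two-sided.  Identical inputs
give t = 0, p = 1; a constant non-zero difference has zero within-pair
variance and is reported as p = 0 with a degenerate-variance flag.

## SNP effects (SNP-BLUP)

Per population and trait, the model is y = Xb + Zg + e with y the
deregressed breeding values, X a column of ones (general mean only), Z the
−1/0/+1 genotype design matrix (kept uncentred; the mean absorbs the
offset), g ~ N(0, I·σ²ₐ/n_snp) and e ~ N(0, D·σ²ₑ), D = diag(1/EDC).  σ²ₐ
is the trait's total additive genetic variance (supplied, in trait units²);
n_snp is the post-intersection marker count, so every marker shares the
prior variance σ²ₐ/n_snp.  σ²ₑ is a configuration input (trait units²); for
synthetic data it is the generator's own residual variance.

The mixed-model equations are solved by iteration on data: Gauss–Seidel
updates of the mean and then each SNP in map order, maintaining the
residual vector e = y − Xb − Zg incrementally after every single-effect
update, so the coefficient matrix is never formed.  Convergence is declared
when the relative L2 change of the full solution over one sweep falls below
`tol` (default 1e−10; update order is irrelevant to the fixed point, which
the tests pin against dense solves of the same equations).  A
constant genotype column has no data contribution and its effect stays 0.

The per-SNP additive variance used in regional comparisons is
âⱼ = 2ĝⱼ²pⱼ(1−pⱼ) with pⱼ the **base-population** allele frequency below.

## Base-population allele frequencies (gene-content BLUP)

The base population is the set of pedigree founders (both parents unknown)
— non-genotyped ancestors of the genotyped sample.  Treating gene content
(0/1/2 copies of the counted allele) as a trait, the model
gc = 1μ + u + e with u ~ N(0, A·σ²ᵤ) is solved on all pedigree animals,
observations present only for genotyped ones; p_base = μ̂/2, clamped to
[0, 1] (BLUP can overshoot slightly).  A⁻¹ is assembled directly from the
pedigree by Henderson's rules with Mendelian-sampling contributions 2, 4/3
and 1 for two/one/zero known parents; inbreeding is ignored — the intended
pedigrees are shallow (2–3 generations), where the distortion is
negligible.  The variance ratio λ = σ²ₑ/σ²ᵤ defaults to 0.01: gene content
is almost perfectly heritable, and as λ → ∞ the estimate degenerates to the
genotyped sample mean over 2 (a tested limit).  One coefficient matrix
serves all SNPs sharing a missingness pattern and is LU-factorised once;
frequencies are estimated per SNP independently.

## Regional comparisons and FDR

Each chromosome is tiled with non-overlapping windows of length L anchored
at coordinate 0 (the anchor is a convention; nothing downstream depends on
it), for L on the grid 0.3–1.5 Mbp in 0.1 Mbp steps.  Within a window the
per-SNP âⱼ of the shared SNPs are averaged per population and compared with

    t = (ā_DE − ā_PL) / sqrt((σ̂²_DE + σ̂²_PL) / N_SNP),

where σ̂²ₓ is the within-window sample variance of the âⱼ.  The statistic's
denominator pools the two variances with a common N, so p-values use a t
distribution with 2·N_SNP − 2 degrees of freedom (Welch df would not match
this denominator).  The tested quantity is the additive variance â by
default — the per-SNP quantity the regional hypothesis is defined on — with
`value="g_hat"` available to test raw effects instead.  Windows with fewer
than two shared SNPs have no defined variance; they are excluded from
testing and from the FDR family.  Significance is controlled per window
length and trait by Benjamini–Hochberg at q ≤ 0.10, matching how the
window-length scan is reported (one BH family per scan point).

## Cross-population (co)variances

Stacking each shared SNP's two effect estimates into a pair y_j, the
bivariate model is y_j = μ + q_j + ε_j with one mean per population,
q_j ~ N(0, G) for a free 2×2 symmetric G (SNPs exchangeable), and
ε_j ~ N(0, σ²ε I₂) with a single residual variance: with one observation
per SNP per population, population-specific residual variances would be
wholly confounded with G's diagonal.  Estimation is EM-REML on the scatter
matrix of the mean-centred pairs (the sufficient statistic), with the REML
log-likelihood monitored and non-decreasing; a G update leaving the PSD
cone is projected back by eigenvalue clipping and flagged.  Derived
quantities: genetic correlation ρ_g = G₁₂/√(G₁₁G₂₂) and variance ratio
G₂₂/G₁₁ (second population over first; DE/PL in the pipeline's ordering).

**Identifiability.**  The marginal covariance of a pair is V = G + σ²ε I₂.
The likelihood therefore depends on (G, σ²ε) only through V: G₁₂ = V₁₂ is
fully identified, but the split of V's diagonal between G₁₁, G₂₂ and σ²ε is
a flat ridge, and ρ_g inherits that indeterminacy.  EM converges to the
ridge point fixed by its starting values — an even split, G⁰ = S/2 and
σ²ε⁰ = tr(S)/4 — which is the package's documented reporting convention,
comparable across runs and traits because it is a deterministic functional
of the data.  Consumers needing split-free quantities should use G₁₂, the
marginal variances V₁₁ and V₂₂, or the raw correlation V₁₂/√(V₁₁V₂₂) (a
lower bound on ρ_g).  General-purpose REML software fitted to this model
faces the same ridge and reports its own algorithm-determined point.

## Synthetic data

The generator emulates the study conditions the analysis assumes, at desk
scale:

- **Frequency spectrum**: ancestral frequencies uniform on [0.05, 0.95] —
  the flat spectrum of an ascertained genotyping array, not a neutral SFS.
- **Drift**: per-population frequencies Balding–Nichols around the
  ancestral value with F = 0.01, giving a cross-population base-frequency
  correlation near 0.97 for closely related populations.
- **LD**: founder haplotypes from a first-order latent Gaussian copying
  process whose adjacent correlation is exp(−rate·d_bp); rates
  {PL: 2.5e−7, DE: 5e−7} per bp, placing LD on the hundreds-of-kbp scale of
  a medium-density array.  The implied r²(d) is not the fitted hyperbola;
  the generator's contract is ordinal — a higher copying rate yields the
  larger fitted β — not a calibrated β value.  (For copying rates fast
  enough that short-range LD is unsaturated, the ordering inverts; the
  defaults sit safely inside the ordinal regime.)
- **Pedigree**: 2 non-genotyped founder/ancestor generations above one
  genotyped generation (400 animals each by default), random mating, gene
  dropping with Haldane recombination at 1 cM/Mbp, so genotypes, haplotypes
  and pedigree are mutually consistent.
- **Effects and proofs**: true per-SNP effects bivariate normal across
  populations with correlation 0.3 and per-population totals
  σ²ₐ = {PL: 1, DE: 2} spread over the panel (DE/PL variance ratio 2, the
  middle of the plausible range for differently selected strains);
  deregressed proofs y = μ + Zg + e with e_i ~ N(0, σ²ₑ/EDC_i), σ²ₑ = 10
  (progeny-test-scale reliabilities), EDC log-normal(meanlog 4, sdlog 0.7).
  A 0.2% missing-call rate exercises the QC and missing-data paths.

One seeded `numpy` generator drives everything, so a seed reproduces a
dataset bit-for-bit.  What the generator does **not** emulate: realistic
recombination maps, mutation, selection, family structure within the
genotyped generation beyond the pedigree, ascertainment beyond the
frequency bound, and any LD between the true effects and the map.  Passing
recovery tests therefore demonstrate internal statistical correctness of
the estimators under their own assumptions, not robustness to the ways
real cattle data violate them.

## Problem sizes and numerical settings

Tests and the acceptance script run at deliberately modest sizes chosen to
make the measured quantities stable: Gauss–Seidel vs dense solves at 200
animals × 500 SNPs (relative error ≤ 1e−6 demanded, ~1e−12 observed);
null-FDR calibration over 20 replicates of 20,000 SNPs in ~1,900 windows;
bivariate fits at m = 10,000 pairs × 20 seeds; base-frequency recovery on
2×120 genotyped animals × 250 SNPs (MAE < 0.05 demanded, ~0.04 observed);
LD β-ordering over 20 replicate datasets of 900 SNPs on 2×30 Mbp
chromosomes.  The window arithmetic is checked at the full published panel
scale (39,557 markers, 3,819 windows of 0.6 Mbp) because it costs nothing.

Degenerate inputs are handled explicitly rather than by exception where a
defined answer exists: all-missing SNPs fail call rate (no 0/0 MAF),
monomorphic loci yield flagged-missing r², constant genotype columns keep a
zero effect, single-SNP windows are excluded from the FDR family, zero
within-pair variance in the paired LD test is flagged degenerate, and a
non-PSD EM update is projected and flagged.

## Known limitations

- Phasing is consumed, not performed; the EM fallback estimates two-locus
  frequencies only (no long-range phase).
- A/T and C/G allele ambiguity is not resolved during harmonisation (the
  generator never produces it; real array data would need strand checks).
- The A⁻¹ assembly ignores inbreeding; deep or inbred pedigrees need the
  inbreeding-adjusted rules.
- ρ_g and the G/σ²ε split in the bivariate model are reporting conventions
  on a likelihood ridge (see above); only V and G₁₂ are data-identified.
- The window t-test treats per-SNP additive variances as exchangeable
  within a window; LD between adjacent SNPs makes them positively
  dependent, so nominal p-values are mildly anticonservative in dense
  windows (the FDR calibration test bounds the practical impact under the
  null).
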