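# Methods

This note documents the models, conventions and numerical choices behind
`haplopheno`, and what the synthetic-data generator does and does not
emulate.

## Coordinates, calls and haplotype strings

Positions are 1-based in VCF and phenotype files and half-open 0-based in
every internal interval (gene spans, coding intervals, region queries);
conversion happens only at the I/O boundary, which keeps boundary SNPs
unambiguous (a SNP at 1-based position p belongs to interval [s, e) iff
s ≤ p−1 < e). Genotypes are unphased diploid states {REF_HOM, HET, ALT_HOM,
MISSING}; phased separators are read as unphased. Multi-allelic records and
indels are excluded on read (a strict flag turns exclusion into an error)
because haplotypes are defined as SNP-allele strings. Strings are always
reported on the forward genome strand regardless of gene strand, so strings
from different catalogues can be compared textually.

Within a gene, an accession contributes a haplotype string only when it is
homozygous at every catalogued locus. The default heterozygote policy
(`EXCLUDE_ACCESSION`) removes the accession for that gene; an alternative
site-level reading (`SITE_DROP`) first removes loci whose heterozygote
frequency exceeds a configurable fraction (default 5%), then excludes
remaining het/missing accessions. Haplotype IDs are frequency ranks
(H1 = most common) assigned per catalogue build, with ties broken by the
earliest carrier's panel index, so output is deterministic but IDs are not
portable across panels; all cross-catalogue comparison goes through the
allele string itself. Haplotypes with fewer than `min_carriers` carriers
(default 3; 5 is exposed as a recommended conservative setting) remain in
the catalogue but are flagged and skipped by the haplo-pheno stage. A gene
with zero polymorphic loci yields one empty-string haplotype carrying every
accession rather than zero haplotypes, so monomorphic genes count as
1-haplotype genes in diversity summaries.

Whether gene haplotypes should use all gene SNPs, coding SNPs only, or a
flanked window is a genuinely open choice; `region_mode` is therefore a
required explicit parameter of the extraction step rather than a default.

## Phenotype model

Plot-level single plant yield (grams) from an augmented RCBD trial is
modelled per season × condition as

    y = μ + block (fixed) + genotype (random, σ²g) + ε (σ²e).

Check and test entries both enter as genotype levels; the check/test
distinction is metadata only. REML is maximised by a bounded Brent search
over log λ ∈ [−10, 10], λ = σ²g/σ²e, with σ²e profiled out analytically.
Because records group by genotype, V = I + λZZ′ is inverted in O(n) via the
Woodbury identity, so a fit on ~1200 plots takes milliseconds. At the lower
search bound σ²g is reported as exactly 0; if the response is literally
constant the fit short-circuits to σ²g = σ²e = 0 with all BLUPs at the mean.
BLUPs are reported on the phenotype scale (fitted population mean + genotype
effect). In the balanced no-block case the estimates reduce to the classical
one-way ANOVA estimators (σ̂²e = MSE, σ̂²g = (MSB − MSE)/r) and the BLUP to
the familiar shrinkage of the accession mean, which the test suite checks in
closed form; unbalanced fits are checked against a dense grid search over λ.

Derived statistics (entry-mean basis, r = harmonic-mean replicates):
GCV% = 100√σ²g/μ̄; repeatability H% = 100σ²g/(σ²g + σ²e/r);
GAM% = 100·k·(H/100)·√(σ²g + σ²e/r)/μ̄ with selection differential k = 2.06
(5% selection intensity, the conventional default). Season BLUPs are
combined per condition by an arithmetic mean; accessions missing a season
use the seasons they have and are flagged. The drought susceptibility index
uses the classical Fischer–Maurer form DSI_i = (1 − Ys_i/Yp_i)/(1 − Ȳs/Ȳp);
it is undefined when the panel-wide stress mean is not below the non-stress
mean, and accessions with non-positive control yield are excluded with a
warning. The association stage defaults to the combined stress-condition
BLUP as its phenotype — the choice is exposed in the config because either
DSI or per-season means are defensible alternatives.

## Mixed-model association

Kinship is the VanRaden centered cross-product K = WW′/(2Σp_j(1−p_j)) on
mean-imputed dosages (het = 1); IBS allele sharing is available as an
alternative. The single-marker model

    y = Xβ + s_j α_j + u + ε,   u ~ N(0, σ²g K)

is solved by eigendecomposing K once, rotating y, X and the dosage matrix,
profiling REML over λ under the null (no-marker) model, and then testing
every marker by generalized least squares with λ held at the null estimate —
the EMMAX/P3D approximation. The test is a Wald F with residual
df = N − rank(X) − 1; X contains an intercept plus the Q matrix with one
column dropped for identifiability. Per-marker PVE is
100·Var(s_j α̂_j)/Var(y). Monomorphic markers are flagged NA, not errors.
The per-marker GLS is vectorised through a Schur complement on the null
cross-products, so a 500-marker scan at N = 300 costs a few milliseconds
beyond the eigendecomposition. Null calibration of the scan (fraction of
p ≤ 0.05 under a phenotype simulated from the fitted covariance) sits within
the binomial 99% band of 0.05 at N = 300, M = 500 — the small residual
liberality expected from estimating K and λ from the same data.

CMLM clusters accessions by average linkage on (1 − K) distance into
`n_groups` (default ⌈N/10⌉, a user parameter rather than
likelihood-optimised — a documented simplification), replaces K by its block
average, and proceeds as above; with one group the random effect collapses
into the intercept and the scan reduces exactly to fixed-effects regression.
MLMM runs forward stepwise selection: scan, admit the lowest-p marker as a
fixed cofactor when it passes the threshold, re-estimate λ, rescan; a
marker's reported p-value is from the step before its inclusion. MTAs are
the intersection of {p ≤ 0.005} across all configured models — the raw
threshold rule, deliberately without multiple-testing correction (Bonferroni
columns are carried for reference only) — and are annotated to every gene
whose span padded by 50 kb contains them, with genic/flanking status.

## Duncan's multiple range test and the SH call

Groups are compared after a one-way ANOVA. For two groups spanning p ordered
means the least significant range is R_p = q(α_p, p, df)·√(MSE/n_h), with
q the studentized-range quantile at Duncan's protection level
α_p = 1 − (1−α)^(p−1) and n_h the harmonic mean of all group sizes (the
usual convention for unbalanced data). Quantiles come from scipy's
studentized-range distribution (numerical integration of the range CDF with
root-finding) and are cached per (α, p, df) since a single evaluation costs
~0.3 s; the test suite validates them against a seeded Monte-Carlo
simulation of the range statistic. Letters use the insert-and-absorb
compact-letter display, which guarantees that two groups share a letter iff
their mean difference is below the applicable R_p. Degenerate inputs: with
MSE = 0, unequal means are trivially separated and equal means share a
letter.

The superior haplotype is the highest-mean group (ties broken by group
name). The default `TOP_SEPARATED` policy calls it when it shares no letter
with at least one other group — matching published haplo-pheno practice,
where an SH may share a letter with the runner-up; `STRICT` demands
separation from every group and is the conservative option. Yield advantage
is reported against two bases, each other group's mean and the pooled
non-SH mean, because no single basis is canonical. Donors are the top-k
SH-group members by BLUP (ties by accession ID); multi-gene SH combinations
are cross-referenced by allele string, never by haplotype ID.

## Validation assignment

Re-sequenced varieties are filtered (calls below depth 10 set missing, loci
below 90% call rate removed — an idempotent operation), then matched exactly
against the catalogue strings. Assignment is deliberately exact-match only:
a string absent from the discovery catalogue is reported `NOVEL` — that is
information about the validation panel, not an error — and het or missing
calls at catalogue loci give `UNASSIGNED` with the reason. SIFT scores are
consumed from upstream tools; < 0.05 is `DAMAGING`, > 0.05 `TOLERATED`, and
the boundary 0.05 (which the usual definition leaves open) is resolved to
`TOLERATED`.

## Synthetic panels

The generator emulates the study system: N accessions (default 399) from
K = 5 subpopulations with fixed proportions (0.35/0.20/0.20/0.15/0.10),
neutral background SNPs with Balding–Nichols allele-frequency divergence
(Fst 0.15), a softened hard-assignment Q matrix (Dirichlet concentration
40), per-gene haplotype spectra, and plot records for two seasons ×
{non-stress, drought} × 3 replicates. Haplotype spectra are realized as
exact carrier counts by largest-remainder rounding rather than multinomial
draws, so a configured 3/399 haplotype reports exactly 0.75% and rare-class
behaviour is reproducible; haplotype h carries the alt allele at tag SNP
h−1 only, giving every non-reference haplotype a private marker (the SH's
tag SNP is the planted causal marker). Heterozygous calls are injected at
2% and missing calls at 0.5% to exercise the exclusion filters.

The phenotype for a plot is condition mean + subpopulation shift + planted
haplotype effects + polygenic value + season shift + block effect +
residual, clipped at 0 g. The polygenic vector has covariance proportional
to the realized neutral-SNP kinship (Cholesky construction), with one shared
draw scaled per condition (genetic correlation 1 across conditions — a
simplification). Planted effects act under drought only, since the genes
being emulated are drought-responsive and the haplo-pheno phenotype is the
drought-season BLUP. Default condition parameters — drought mean 4.5 g
(polygenic sd 1.8, subpop sd 0.8, residual sd 1.4) vs non-stress 15.0 g
(2.8/1.5/3.4) — put the drought GCV near 45% and the non-stress GCV near
25%, reproducing the qualitative structure of drought trials (lower mean,
larger genotypic CV, repeatability above 60%); generated repeatabilities run
somewhat higher than typical field values because the generator has no
spatial trend or measurement-protocol noise. All randomness derives from one
integer seed through fixed-key child streams, so adding a gene does not
perturb earlier genes' draws and identical configs give byte-identical
output files.

The planted-effect scenario used for end-to-end power checks
(`planted_sh_config`) carries one gene whose superior haplotype has 10
carriers and a +1.5 g drought effect, with plot residual sd 1.0 g and
deliberately small background variance (polygenic sd 0.5, subpop sd 0.3) so
the stated residual dominates the within-group spread of combined BLUPs.

What the generator does **not** emulate: linkage disequilibrium between
genes or with the neutral background (genes are unlinked, so planted-marker
recovery is not confounded by LD shadows), coalescent realism, genotype ×
environment interaction beyond condition-specific means and variances, and
spatial field heterogeneity. Passing tests therefore demonstrate the
statistical machinery under a correctly specified structured model, not
robustness to those real-data complications.

## Problem sizes in the test suite

Simulation-backed checks run at the sizes the analyses target where that is
cheap (399-accession planted-recovery over 100 seeds; N = 300, M = 500 null
calibration over 100 runs; 500 null group sets for the SH false-call rate)
and at reduced sizes for purely structural properties (the stress-vs-
non-stress GCV ordering uses 30 seeds at N = 200; the Monte-Carlo quantile
oracle uses 4×10⁵ draws; REML parameter recovery uses 60 seeds). The
acceptance script reports planted recovery over 30 seeds and null
calibration over 20 runs, which keeps its full run under a minute.

## Known limitations

* Haplotype blocks are whole-gene SNP sets; no LD-based block definition or
  statistical phasing of heterozygotes.
* CMLM's group count is not likelihood-optimised; MLMM uses a fixed
  inclusion threshold rather than model-selection criteria (extended BIC).
* The EMMAX approximation holds λ at its null estimate per scan; markers
  with very large effects are slightly conservative relative to exact EMMA.
* DSI is a ratio index and inherits instability when control yields are
  near zero; such accessions are excluded with a warning.
* The augmented-design model treats checks and tests identically; no
  spatial correction is applied.
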