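# Methods

## Model and procedure

The package treats a phenotyped diversity panel as a segregating population
whose historical recombination lets extreme-phenotype pooling expose
trait-associated allele-frequency shifts. The analysis has three stages.

**Bulk construction.** With bulk fraction *f* (default 0.20) and panel size
*n*, the bulk size is *k* = round-half-up(*f·n*). Round-half-up is the only
rounding consistent with bulk sizes of 76 and 78 for panels of 378 and 389
at *f* = 0.20 (flooring would give 75 and 77). The low/high bulks are the
order statistics of the trait; boundary ties are broken by accession-id
lexical order so runs are reproducible. The random bulk is drawn uniformly
without replacement from the *entire* panel — extreme accessions are not
excluded — and, when `match_random` is on (the default), redrawn up to 200
times until both its mean and median fall within 0.25 panel SD of the
panel's; otherwise the best attempt is kept with a warning. The random draw
is governed by a single integer seed.

**Pooling and filtering.** Pooled counts per SNP and bulk are
alt_b = Σ dosages over called members and depth n_b = 2 × called members,
so ref_b + alt_b = 2 × called holds identically. The total depth of a SNP is
the allele copies summed over the three bulks (≤ 6k). A frequency-weighted
"depth" expression would be dimensionless; depth here is therefore defined
as the count-bearing quantity, which is what the secondary filter needs.
SNPs are retained iff pooled MAF ≥ `maf_min` (default 0.05) and total depth
≥ `depth_min` (default = k). MAF is computed on the pooled bulk counts —
the quantity the association actually sees — not on the full panel. No
missingness filter is applied: a rare allele present in a handful of
accessions should survive into the association even if the site is poorly
called elsewhere.

**Association.** Bulks are coded 0/1/2 with the random bulk at the
midpoint; equal spacing is the minimal reading of "the bulks as a linear
sequence" and makes the control bulk a trend anchor. The default model is a
binomial GLM on the pooled counts, fitted by damped Newton scoring
(equivalently IRLS) on the two parameters (α, β); using counts rather than
the three frequencies exploits the depth information and leaves a proper
likelihood (three frequency points alone leave one residual df). The Wald
statistic (β/se)² is referred to χ²₁, two-sided; the direction of the trend
is reported through the sign of β rather than by one-sided testing.
Quasi-separated SNPs (monotone 0→1 frequencies) are handled by step damping
(max Newton step 8) and capped iterations (60); non-converged fits are
flagged `separated` but still return finite estimates. SNPs monomorphic
after pooling are skipped. A weighted-least-squares alternative
(`wls_freq`: alt frequency on bulk code, weights = depth, error variance
from the single residual df) is retained because the bulk-trend idea is
sometimes run as plain least squares; the two models agree in the sign of β
on simulated panels and the binomial route is the default. The per-SNP "R²"
column is McFadden's pseudo-R² (1 − ℓ/ℓ₀ with full binomial likelihoods);
this definition is an interpretive choice and is labelled as such.

Stratification is handled solely by genomic control in the Devlin–Roeder
median form: λ = median(χ²)/0.4549, clamped at λ ≥ 1 so adjustment never
makes p-values more significant; adjusted p comes from χ²/λ on 1 df. No
further multiple-testing correction is applied: MTAs are called at the
fixed genome-wide cutoffs 10⁻⁴ (primary) and 10⁻⁶ (stringent), a deliberate
departure from Bonferroni-style control in favour of rare-variant recall.

PVE per SNP is computed from the full expression
2β²·MAF(1−MAF) / [2β²·MAF(1−MAF) + 2·se²·N·MAF(1−MAF)]; both it and its
algebraic simplification β²/(β² + N·se²) are evaluated and asserted equal.
*N* is the number of phenotyped panel accessions (not the number of bulks
or 2k): PVE is reported as panel-level variance explained.

**Candidate genes and overlap.** LD is the squared Pearson correlation of
unphased dosages over pairwise-complete accessions (composite LD); the
3K-style inputs are unphased, so gametic-phase EM estimation is out of
scope. r² is computed against the full panel, not bulk members. The scan
window is ±50 kb around the peak (clipped at position 1); window SNPs with
r² ≥ 0.4 are intersected with gene intervals, and the gene harbouring the
peak itself is always reported. Cross-run overlap uses fixed-origin 1-based
bins [1..100000], [100001..200000], … (index floor((pos−1)/bin size));
fixed-origin bins are deterministic where MTA-centred pairing would depend
on which set anchors the window, and the window operation covers the
MTA-centred reading.

**Haplo-pheno.** Gene-region calls map to symbols R/H/A (hom-ref, het,
hom-alt); heterozygotes are a distinct symbol rather than IUPAC-expanded,
and accessions with any missing call in the region are excluded rather than
imputed — in a selfing-crop panel imputation would fabricate haplotype
identity. Haplotypes are distinct symbol strings; singletons are kept at
collapse and dropped by the ≥ 2-carrier filter before testing. Duncan's
multiple range test uses accession-level trait values as observations, the
one-way ANOVA error mean square (df = Σ(nᵢ−1)), critical ranges
R_p = q*(p, df, α_p)·√(MSE/ñ) with protection level α_p = 1−(1−α)^(p−1),
studentized-range quantiles from `scipy.stats.studentized_range`, and the
harmonic mean ñ of the group sizes in each stretch for unequal groups. A
stretch of consecutive sorted means whose range is within R_p is
homogeneous and its inner pairs are not separated; maximal homogeneous
stretches receive the display letters. Mean ties are broken by group size
(larger first) then haplotype string. If MSE = 0 the groups are degenerate
and letters follow mean equality. A haplotype is superior when its mean
strictly exceeds panel mean + k_sd × panel SD (k_sd default 1.0) *and*
carries the top letter; "one above the mean" is ambiguous between one SD
and one trait unit, so an absolute-offset mode (`mode="absolute"`, +1 trait
unit) is provided and neither reading is claimed canonical — the SD reading
is the default because it is scale-free. Donors are the union of superior
groups' members, ranked by number of superior haplotypes carried, then
trait value.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| `fraction` | 0.20 | of panel | bulk-size comparison across 10/15/20% favours 20% for segregating panels |
| `maf_min` | 0.05 | frequency | pooled MAF floor; below it counts are too sparse to test |
| `depth_min` | bulk size k | allele copies | secondary coverage filter against pooling error |
| `thr_primary` / `thr_secondary` | 10⁻⁴ / 10⁻⁶ | p | fixed genome-wide tiers; no Bonferroni |
| `r2_min` | 0.4 | — | high-linkage cutoff for candidate SNP extraction |
| `half_width` | 50,000 | bp | 100-kb window centred on the MTA |
| `bin_size` | 100,000 | bp | overlap bin, matching typical crop LD extent |
| `duncan_alpha` | 0.05 | — | test level of the multiple range test |
| `min_members` | 2 | accessions | haplotypes carried by a single accession are not tested |
| `k_sd` | 1.0 | panel SD | superiority margin over the panel mean |

## Synthetic panels

`simulate_genotypes` draws per-SNP ancestral frequencies uniformly on
`maf_range` (default 0.05–0.5) and, for divergence F = `fst` (default 0.1),
subpopulation frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F) — the
Balding–Nichols model, the minimal generator whose PCA reproduces the
3-cluster picture of a rice-like panel. Diploid dosages are Binomial(2, p_s)
per accession. Causal SNPs may be forced to a target frequency (rejection
sampling, tolerance ±0.02, ≥ 2 carriers, 200 attempts) so rare variants
exist in finite panels. Local LD is induced by copy-with-mutation tiling:
the 8 SNPs on each side of a causal site copy its column per accession with
probability 0.9, giving r² ≈ 0.8 in the block so the candidate-gene scan has
signal. Phenotypes are y = Σβ_j g_j + shift(subpop) + ε with ε Gaussian and
σ² = var(g)(1−h²)/h², so realized heritability matches the target up to
sampling; the baseline of 3.5 trait units mimics a grams-scale yield trait.
An optional exponential transform produces right-skewed traits.

The standard fixture — n = 300 accessions, 5,000 SNPs, three clusters
(F_ST 0.1, phenotype offsets −0.3/0/+0.3), one common causal (frequency
0.30, effect 1.0) and one rare causal (frequency 0.03, effect 3.0), h² =
0.4 — is sized so that a full simulate-and-associate replicate runs in well
under a second, letting calibration and power checks average over dozens of
seeds; the acceptance script uses 50 replicates.

What the simulator does *not* emulate: read-level sequencing (pooling here
is exact genotype counting, not DNA-pool sequencing), genome-wide
recombination-map LD (only local blocks around causal sites), multiallelic
sites, genotyping error, and the long-tailed skew of real yield-under-stress
data unless the transform is enabled. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not performance on any real panel.

## Numerical choices

- Newton scoring converges when the max parameter step < 1e-10; steps are
  damped to 8 per iteration; bulks with zero depth carry zero weight and
  drop out of the 2×2 information matrix, which is inverted in closed form
  across all SNPs at once.
- λ is computed on the retained SNPs' Wald statistics; below 100 SNPs a
  warning is emitted because the median is unstable.
- PVE inputs are validated (se > 0, 0 < MAF ≤ 0.5, N ≥ 1); the two formula
  forms are compared at rtol 1e-12.
- r² over pairwise-complete accessions returns 0 (flagged) when either
  site is monomorphic on the complete pairs, and errors below 2 pairs.
- Duncan quantiles are cached per (span, df, α); the letter display derives
  from maximal homogeneous stretches, so the "groups sharing no letter
  differ" reading is exact by construction.
- All randomness (bulk draws, simulation) flows through
  `numpy.random.default_rng` seeded from user-supplied integers; reruns are
  bit-identical.

## Known limitations

- No kinship/mixed-model correction: stratification control is genomic
  control only, which deflates uniformly and can under-correct localized
  structure confounding.
- The GLM treats the three bulk counts as independent binomials; the random
  bulk may share accessions with the extremes, inducing slight correlation
  that genomic control absorbs in practice.
- With exactly three bulks the WLS variant estimates its error variance
  from a single residual degree of freedom; it is retained for comparison,
  not recommended.
- Multiallelic records are dropped, not split.
- Precomputed bulk-frequency tables are not accepted as input; pooled
  frequencies are always recomputed from genotypes.
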