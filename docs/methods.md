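# Methods

## Scope and data model

The package analyses imputed HLA dosage data at three variant resolutions.
Two-field alleles (e.g. `DRB1*04:01`) are the primitive inputs; one-field
alleles are sums of their members, and amino-acid markers are sums of the
alleles carrying a given residue at a given position.  Both derivations are
exact linear aggregations, so they apply identically to hard genotype calls
and fractional imputed dosages, and they conserve the per-locus dosage total
(2 per individual for a complete call set) to numerical precision — a
property the test suite checks at 1e-9 on every simulated cohort.

Deletion characters in allele sequences are treated as ordinary residue
codes and produce their own markers; indel polymorphism is real HLA
variation and needs no special casing.  Grouped-residue markers (one marker
for a residue *set*, as in panel names like `AA_DRB1_position13_exon2_FLS`)
are supported as an opt-in: the default encoding is one marker per residue,
since the joint encoding is a panel convention rather than a modelling
choice.

Variant filtering retains MAF ≥ 1% and imputation R² ≥ 0.7 by default, both
bounds inclusive.  A variant with no R² (anything that never passed through
an imputation step, including all derived markers on synthetic data) passes
the R² filter with a logged warning rather than failing hard.  The MAF
filter is applied after derivation, on the derived dosages.  When metadata
lack a MAF it is computed as mean(dosage)/2 folded to ≤ 0.5.

Genomic annotation uses 1-based inclusive coordinates; a pGene is *cis* when
its interval overlaps the extended MHC (chr6:28,000,000–34,000,000, hg19)
and *trans* otherwise.  Peptide-binding-groove membership of an amino-acid
marker depends only on its locus class and exon: exons 2 and 3 for class I,
exon 2 for class II.

## Phenotype preparation

Order of operations: inverse rank-normal transform → (optional) protein
expression PCs → residualization → scaling → LOCO subtraction.

- **INT** maps ranks to Gaussian quantiles with the Blom offset (3/8), the
  common convention in pQTL work; the offset is a parameter.  Ties share
  average ranks; missing values stay missing.
- **Expression PCs** are computed once on the INT-transformed matrix with
  per-protein mean imputation (a PCA needs a complete matrix), then appended
  to the covariates and removed in the same single residualization pass as
  everything else.  Component signs are fixed by making the largest-
  magnitude loading positive, so results are reproducible across runs.
- **Residualization** is complete-case per protein; covariates must be
  complete.  Categorical covariates expand to indicators; columns aliased
  with earlier ones are dropped with a log message, and a design still
  rank-deficient after that is an error naming the aliased columns.
- **Scaling** z-scores the residuals (population SD), after which the LOCO
  offset — a per-protein, per-individual polygenic prediction computed
  upstream, zero when absent — is subtracted.  A flag switches to
  subtract-before-scale for sensitivity checks.

Per-variant models run on the prepared phenotype with only run-specific
covariates (e.g. a cohort indicator in pooled analyses) re-entering; a flag
allows re-entering the full covariate set instead.  Since OLS residualization
is a projection, the two parameterizations give identical dosage
coefficients when the same covariates are used; the single-pass default just
avoids refitting nuisance columns thousands of times.

## Association tests

Single-marker tests are OLS with the dosage term partialled against the
intercept and any covariates (Frisch–Waugh), which is algebraically the full
multivariable fit.  Two-sided p-values are carried as −log10 p throughout.
Where `scipy`'s log survival functions lose accuracy (roughly below
p = 1e-280) the tail is computed from the regularized incomplete beta
function in log form, `I_x(a,b) = x^a (1-x)^b 2F1(a+b,1;a+1;x) / (a B(a,b))`,
which agrees with R's `pt(..., log.p=TRUE)` to seven significant digits out
to −log10 p ≈ 1000.  A numerically perfect fit reports a configurable cap
(default 5000) rather than infinity.

Thresholds: the discovery threshold for lead pQTL is 5×10⁻⁸ divided by the
number of proteins tested; conditional rounds (single-marker and omnibus)
use 5×10⁻⁸ undivided.  Lead selection is maximal −log10 p, ties broken by
larger |β|, then lexicographic variant id — deterministic and documented,
since published analyses rarely state a tie rule.  Complete cases are
evaluated per (protein, variant) pair with n reported per test; a minimum of
10 complete cases is enforced, and a constant dosage yields a flagged-skip
result instead of an exception.  Conditional rounds do not re-filter
candidates by MAF.

Forward conditional scans stop at the threshold or when every remaining
candidate is aliased with the conditioning set (skipped, logged).  The
class-adjusted sensitivity test conditions a lead on all two-field alleles
of the opposite HLA class, dropping the lowest-frequency allele per locus as
the reference (the per-locus dosages sum to 2) plus any further aliased
columns.  The combined model co-fits the HLA lead with an external variant
(e.g. a class III SNP pQTL) and labels the outcome hla_driven /
external_driven / both_independent / neither at a given significance level;
a pair with |r| > 0.999 is flagged collinear and labelled neither, since the
data cannot separate signals in that much LD.

Variance decomposition is sequential Type-I sums of squares over the nested
model sequence in lead-then-conditional order: fraction_k =
(RSS_{k−1} − RSS_k)/TSS, so the total equals the joint-model R² exactly; an
aliased variant contributes 0 with a log message.  Permutation nulls shuffle
the fully prepared phenotype across individuals — covariate structure stays
fixed, which is the correct null for models run on residualized phenotypes —
and the empirical p uses the add-one rule (1 + #{null ≥ observed})/(1 + B).

## Conditional-haplotype fine-mapping

The omnibus test at a position compares covariates + conditioning columns +
(M−1) residue-group columns against the same model without the group
columns, by an F test with the p-value in log space.  The dropped reference
group is the most frequent residue (deterministic; ties alphabetical).
Group columns collinear with the conditioning set are dropped and df1
reduced; df1 = 0 means the position is untestable after conditioning and
returns a no-test marker, not an error.  Group dosages (sums of allele
dosages) are used rather than phased best-guess genotypes: the two coincide
on hard calls, and dosages keep one code path for soft calls.

Sequential fine-mapping scans all polymorphic positions at all loci in round
one, then restricts to the lead's locus — or to all of DRB1, DQA1 and DQB1
when the lead falls in that superlocus, whose tight LD makes per-locus
attribution unreliable — conditioning on every previously selected
position's grouping.  The chain stops at non-significance or after three
conditionally independent positions.

A structural caveat, visible in the synthetic experiments: at a biallelic
position the two residue markers are complementary (their dosages sum to the
locus total), so single-marker scans may report either coding of the same
contrast, with mirrored sign.  Recovery should therefore be judged at the
position/contrast level, as the omnibus test does.

## Synthetic cohorts

The generator draws two gametes per individual (Hardy–Weinberg).  The
DRB1–DQA1–DQB1 superlocus is drawn jointly from a haplotype frequency table,
which directly induces its LD and yields phased haplotypes for the
conditional-haplotype logic; all other loci draw independently from allele
frequencies.  Observed dosages add truncated Gaussian noise (clipped to
[0, 2]; SD 0.05 by default, putting true–observed r² near 0.99 for common
alleles, consistent with the R² ≥ 0.7 regime of filtered imputation panels).
Phenotypes are additive in the *true* dosages plus covariate effects and
N(0, 1) noise; measurements go missing completely at random at rate 0.032,
a typical mean per-protein missingness for plasma proteomic panels.  One
global seed splits into per-purpose streams (haplotypes, dosage noise,
covariates, phenotype noise, missingness) so toggling one component leaves
the rest reproducible.

The bundled catalog is synthetic: real allele nomenclature, 2–6 alleles per
locus, a handful of polymorphic positions each, frequencies loosely shaped
like a European cohort with all alleles ≥ 1%.  The residue assignments were
designed so that each causal carrier set used in the tests is identified by
exactly one marker (no other position's group, or complement of a group,
duplicates it) — real panels have hundreds of positions and much richer
aliasing.  What passing tests show is therefore that the estimators are
correct and the scans recover identifiable architecture at realistic effect
sizes; they do not show that every real HLA signal is identifiable, and the
generator makes no attempt at population structure, relatedness, selection,
or informative missingness (LOCO offsets, which absorb the former two in
real studies, are accepted as inputs and default to zero).

## Problem sizes and numerical choices

Default experiment sizes: recovery experiments use cohorts of 2000–3000
individuals and 100 replicate seeds (40 in the acceptance script); the null
calibration uses 2000 individuals × a few hundred proteins; permutation
checks use 1000 permutations.  These sizes give the scans comfortable power
at the 0.3–0.4 SD effects used, while keeping the full suite in the
low minutes on one CPU.  Collinearity tolerances: partial variance below
1e-10·n marks a column constant/aliased; QR with column pivoting (relative
diagonal threshold 1e-8) detects rank deficiency in covariate designs.
Dosage conservation and R²-identity assertions use 1e-9/1e-8 absolute
tolerances; oracle-equivalence tests use 1e-8 relative.

## Known limitations

- No mixed models or whole-genome regression; LOCO offsets are inputs.
- No Bayesian fine-mapping or colocalization; overlap with external
  fine-mapped trait tables is a join on a documented variant-id
  normalization (`LOCUS_pos_RESIDUE`), not a statistical colocalization.
- The Fisher odds ratio is the sample (a·d)/(b·c) with zero cells flagged
  (inf/nan) rather than continuity-corrected.
- Catalog parsing is limited to this package's JSON format; IPD-IMGT/HLA
  alignment releases must be converted upstream.
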