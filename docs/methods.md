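# Methods

This note records the statistical definitions, conventions and design
choices behind `codonusage`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence model and inclusion filters

A coding sequence is accepted if its length is a positive multiple of
three, it contains only A/C/G/T, and it has no internal stop codon
(TAA/TAG/TGA). Input is case-normalised to upper case; `U` is treated as
an ambiguous base rather than silently converted, because the sequence
contract is DNA. An ATG start is deliberately **not** required: panels
assembled from annotation databases occasionally carry non-AUG starts or
trimmed 5′ ends, and rejecting on the start codon would silently drop
genes. A terminal stop codon is retained for nucleotide-level statistics
(composition, dinucleotide odds) and stripped for everything defined on
amino-acid-coding codons (translation, RSCU, ENc, CAI). Rejected records
are reported with a single reason code each, assigned in the fixed order
EMPTY → NOT_MULTIPLE_OF_3 → AMBIGUOUS_BASE → INTERNAL_STOP.

## Composition

Percent base composition is computed overall and per codon position over
the full CDS (terminal stop included, consistently with the retention
rule above). GC12 is defined as the arithmetic mean of GC1 and GC2 —
with complete codons the position classes are equal-sized, so this
coincides with the GC fraction of concatenated positions 1+2, but the
mean is the documented definition. `gc3_synonymous` additionally offers
GC3 over synonymous codons only (ATG, TGG and stops excluded), the
convention under which the ENc drift null is exact; the pipeline default
for the ENc–GC3 plot is the plain all-codon GC3, with the policy
recorded in the output metadata and switchable per run.

## RSCU

RSCU(c) = n_c / (N_aa / deg(aa)) over the 59 codons of the 18 degenerate
families. When a family is absent the entire family is flagged MISSING
rather than zero-filled, because "unused synonym" and "amino acid not
present" are different facts. Classification thresholds are the
conventional 1.6 (over) / 0.6 (under); they are configuration values in
the pipeline and constants in the library.

## ENc

Wright's estimator with six-fold families (Leu, Ser, Arg) kept whole,
matching the CodonW default. Amino acids with n < 2 occurrences are
skipped (F is undefined at n = 1). If the single three-fold family (Ile)
is missing, F̄₃ is imputed as (F̄₂+F̄₄)/2 — Wright's own recommendation;
if any other degeneracy class cannot be estimated the gene's ENc is
reported as undefined (`None`) and excluded from panel correlations
instead of being guessed. The raw value is clamped to [20, 61]; the
estimator can exceed 61 by sampling noise in near-uniform genes, and the
clamp keeps reported values inside the interpretable range.

## CAI

Relative adaptiveness weights are w(c) = RSCU_ref(c)/max RSCU_ref within
the family, built by pooling codon counts over a reference gene set. No
reference usage table is bundled: the natural references differ by
application (the panel itself, a highly-expressed gene set, a genome
table), so the default pools the analysed panel and any tabulated
reference can be loaded from TSV. Codons unseen in the reference receive
the pseudo-weight 0.5/(family total) so geometric means stay positive; a
family wholly absent from the reference is uninformative and weights 1.

`cai59` is the classical geometric mean of w over all codon occurrences
in degenerate families. `cai18` is an amino-acid-composition-corrected
variant: the geometric mean of w within each family present, averaged
over families, so that one abundant amino acid cannot dominate the
index. Published tools compute composition-corrected CAI variants in
more than one way; the per-family-mean definition used here is exactly
what the code implements and should not be assumed identical to any
specific external tool.

## Dinucleotide odds ratios

ρ(xy) = f(xy)/(f(x)f(y)) with pair frequencies over all overlapping
adjacent positions of the given strand (codon boundaries included, no
wrap-around) and base frequencies over the whole sequence. No
reverse-complement symmetrisation is applied — CpG and GpC are
biologically distinct signals and a symmetrised measure would collapse
them. Ratios involving a base of frequency zero are MISSING.
Classification thresholds: 0.78 / 1.23.

## Force attribution

*Neutrality plot.* Ordinary least squares of GC12 (response, percent) on
GC3 (predictor, percent) across genes. The slope is reported both raw
and as the conventional percentages 100·slope ("mutation") and
100·(1−slope) ("selection"). The regression requires ≥ 3 genes and
non-degenerate GC3; violations raise rather than returning NaN.

*ENc–GC3.* The drift null ENc*(s) = 2 + s + 29/(s²+(1−s)²). Because
float equality to a curve is meaningless, a configurable tolerance band
(default ±0.5 ENc units) defines "ON"; genes beyond it are BELOW
(selection) or ABOVE. The ±0.5 default is narrow relative to the
ENc scale and wide relative to float noise; it is a display convention,
not an inference procedure.

*Parity rule 2.* x = A3/(A3+T3), y = G3/(G3+C3) from third-position
composition only; the panel summary is mean ± SD per axis with
undefined-denominator genes dropped.

*Third-position regressions.* Per nucleotide N, OLS of overall %N on
%N3; R²·100 is echoed in the output as a "mutational force percent"
column because that reading is conventional in the field. The package
reproduces the convention without endorsing R² as a force decomposition.

## Multivariate statistics

PCA of the genes × 59 RSCU matrix is covariance PCA (column-mean
centred, unscaled): RSCU values share one scale and standardising would
inflate rare-codon noise. MISSING entries are imputed as 0 before
decomposition — an absent family contributes no usage signal. Axis signs
are fixed by making the largest-magnitude loading on each axis positive,
so scores are reproducible across SVD implementations. Correlations are
Pearson r with two-tailed p from the t distribution on n−2 df, pairwise
deletion of missing rows, and stars at p < 0.05/0.01/0.001/0.0001 from
raw p-values; a Benjamini–Hochberg q column is available but optional,
since conventional reports in this literature use raw thresholds.

## Protein indices

Translation uses the standard genetic code. GRAVY (Kyte–Doolittle),
aromaticity, the Guruprasad instability index (DIWV dipeptide weights)
and the isoelectric point (Bjellqvist pKa set, solved by bisection) are
delegated to Biopython's ProtParam machinery, which carries the
published tables. The aliphatic index uses Ikai's coefficients
100·(x_A + 2.9·x_V + 3.9·(x_I + x_L)). "Hydrophobicity percent" is the
percent of residues in {A, C, F, I, L, M, V}; web tools compute a
"hydrophobicity index" under various unnamed scales, so the residue set
is an explicit, configurable stand-in rather than a claimed match to any
particular tool. Residue classes: acidic {D, E}, basic {K, R, H}
(histidine counted basic), neutral the rest. Instability > 40 is
labelled unstable.

## Synthetic panel generator

The generator produces CDS panels whose force structure is known, so
that recovery of that structure by the analyses is a meaningful test.

**What it emulates.** Panel size (default 42 genes), gene lengths
(150–3000 codons, uniform), per-gene GC3 targets spanning 0.31–0.84, a
neutrality relation GC12 = m·GC3 + c + ε with m = 0.27, c = 32 percent
and ε ~ N(0, 4) by default — the force geometry of a human disease-gene
panel — plus optional codon preference of strength κ and CpG/TpA
odds-ratio targets.

**Mechanism.** Per gene: (1) third-base weights u (G/C mass) vs 1−u
(A/T mass), with the G-vs-C split γ, define within-family codon
probabilities, multiplied by exp(κ) on one preferred codon per family;
u is solved by bisection so the expected all-codon GC3 equals the
target, γ so that expected G3 = C3. (2) Amino-acid frequencies are
exponentially tilted along two directions and solved by bisection: the
per-amino-acid expected position-1/2 GC content (to hit the GC12
target — positions 1/2 belong to the protein, so GC12 must be steered
through composition) and the per-family A3−T3 excess (to restore the
parity null A3 = T3: the genetic code has six T/C-ending two-fold
families but only three A/G-ending ones, so a uniform composition sits
visibly off the PR2 origin; balancing through composition keeps
within-family usage even and ENc at its drift value). Calibrations
iterate three rounds of coupled bisections, tolerance 1e−7. An
infeasible GC3 target (outside the range achievable under the given
preference and composition) raises an error naming the conflicting
parameters; an unreachable GC12 target is clipped to the achievable
boundary and recorded in the ground-truth record. (3) The protein is
sampled i.i.d. and codons are drawn per family.

**Dinucleotide shaping.** A suppression factor s < 1 is interpreted as a
*target odds ratio*. Synonymous codons are resampled by checkerboard
Gibbs sweeps — even- and odd-index codons are conditionally independent
given the other parity, so each half-sweep is an exact Gibbs update —
where every CpG/TpA occurrence (within codons and across boundaries)
multiplies a codon's weight by a factor. Because the factor does not map
one-to-one onto the realized ratio (suppressing CpG also depletes C and
G, which feeds back through the denominator), the factor is corrected
multiplicatively against the measured ratio over five rounds. The
protein is never modified. A factor of exactly 1 performs no shaping;
the natural ρ(CG) of codon-structured sequence sits somewhat below 1
even then, purely from codon-position composition structure.

**Determinism.** A panel-level generator draws lengths and GC3 targets;
each gene then uses the substream seeded by (seed, gene index), so a
gene's sequence does not depend on how much randomness other genes or
optional stages consumed. Same spec ⇒ byte-identical FASTA.

**What it does not emulate.** Real amino-acid composition (composition
is uniform before calibration tilts), isochore/regional structure along
a gene, splice or UTR context, phylogenetic correlation between genes,
and expression-correlated bias. Passing recovery tests therefore shows
the estimators are correct and well-calibrated under the generative
model, not that real panels satisfy that model.

## Problem sizes used in validation

The recovery analyses use 500 genes of 300–1500 codons for the
neutrality slope (recovered within ±0.05 of the true 0.27), six
preference strengths × 15 genes × 400 codons for the ENc–bias
monotonicity (Spearman), and five ~10 kb genes for the CpG odds target
(realized within ±0.05 of 0.5). The acceptance script re-runs these
together with the full 42-gene study-shaped analysis in under a minute
on one CPU.

## Known limitations

- CAI18 is a documented in-package definition, not a clone of any
  external tool's composition-corrected CAI.
- The ENc clamp discards information above 61 (relevant only to
  near-uniform genes); family-mean imputation for missing Ile follows
  Wright but is still an imputation.
- Reading neutrality slopes and per-nucleotide R² as "percent mutation
  force" inherits the field's convention; the numbers are regression
  summaries, not a causal decomposition.
- The generator's GC3 feasibility range depends on amino-acid
  composition (Met/Trp force G3); targets below ~0.1 at uniform
  composition are correctly rejected as infeasible.
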