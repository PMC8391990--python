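# codonusage

Codon-usage-bias analysis for gene panels.

Synonymous codons are not used uniformly. The pattern of that bias in a
set of coding sequences carries information about the forces that shaped
the genes: directional mutation pressure (visible at largely neutral
third codon positions), translational/functional selection (visible as
codon preference beyond what composition explains), and compositional
constraint. `codonusage` computes the standard battery of statistics
used to dissect these forces on a panel of 40–50 human-gene-sized CDS —
the setting of comparative studies of disease gene panels — and ships a
synthetic panel generator with known ground truth so every stage can be
validated without downloading anything.

## What it computes

Per gene:

- **Composition** — %A/%C/%G/%T overall and at each codon position;
  GC, GC1, GC2, GC3, and GC12 = (GC1+GC2)/2.
- **RSCU** — relative synonymous codon usage for the 59 codons in
  degenerate families (61 sense codons minus ATG and TGG):
  RSCU(c) = observed count / (family total / degeneracy). Values > 1.6
  are over-represented, < 0.6 under-represented.
- **ENc** — Wright's effective number of codons from family
  homozygosities F = (n·Σp² − 1)/(n − 1):
  `ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, in [20, 61]
  (20 = one codon per amino acid, 61 = uniform synonymous usage).
- **CAI** — codon adaptation index, the geometric mean of relative
  adaptiveness weights w(c) = RSCU_ref(c)/RSCU_ref,max. `cai59` runs
  over all codon occurrences; `cai18` averages per-family geometric
  means over the 18 degenerate families, damping amino-acid-composition
  effects.
- **Dinucleotide odds ratios** — ρ(xy) = f(xy)/(f(x)·f(y)) over
  overlapping pairs; < 0.78 under-represented, > 1.23 over-represented
  (CpG/TpA suppression being the classic signals).
- **Protein indices** — GRAVY, aromaticity, isoelectric point,
  aliphatic index, hydrophobic-residue percent, Guruprasad instability
  index (> 40 ⇒ unstable), and acidic/basic/neutral residue counts.

Per panel:

- **Neutrality plot** — OLS of GC12 on GC3; 100·slope is read as the
  percent contribution of mutation pressure, the remainder as selection.
- **ENc–GC3 plot** — observed ENc against Wright's drift expectation
  `ENc*(s) = 2 + s + 29/(s² + (1−s)²)`; genes below the curve indicate
  selection on codon choice.
- **Parity rule 2** — x = A3/(A3+T3) vs y = G3/(G3+C3) with panel
  mean ± SD; (0.5, 0.5) is the no-asymmetry point.
- **Per-nucleotide regressions** of overall composition on
  third-position composition.
- **PCA** of the genes × 59 RSCU matrix (covariance PCA, deterministic
  axis signs) with scores, loadings and variance fractions.
- **Correlation reports** (Pearson r, two-tailed p, significance stars,
  optional Benjamini–Hochberg column) among composition, bias,
  expression proxies and protein indices.

## Worked example

```python
import codonusage as cu

spec = cu.SyntheticPanelSpec(n_genes=42, seed=7)   # study-shaped panel
panel = cu.generate_panel(spec)

profile = cu.CodonUsageProfiler().fit_transform(panel)
fit = cu.NeutralityRegression().fit(profile["GC3"], profile["GC12"])
matrix = cu.RscuVectorizer().fit_transform(panel)
pca = cu.pca_rscu(matrix)

print(f"ENc    mean {profile['enc'].mean():.2f}")
print(f"neutrality: GC12 = {fit.slope_:.4f} GC3 + {fit.intercept_:.2f}"
      f"  (R^2 = {fit.r_squared_:.3f})")
print(f"mutation {fit.pct_mutation_:.1f}%  selection {fit.pct_selection_:.1f}%")
print(f"PCA axis 1: {pca.variance_fraction[0]:.2f}%")
```

prints

```
ENc    mean 54.44
neutrality: GC12 = 0.2906 GC3 + 31.57  (R^2 = 0.592)
mutation 29.1%  selection 70.9%
PCA axis 1: 72.41%
```

The generator drew 42 genes whose GC12 follows the line
0.27·GC3 + 32 with Gaussian scatter; the neutrality regression recovers
a slope near 0.27, i.e. ~29% of codon-position coupling attributable to
directional mutation and ~71% to selection, and the first RSCU principal
axis is dominated by the GC3 gradient across genes.

The same analyses run from the shell on any CDS FASTA:

```bash
codonusage run --fasta panel.fasta --outdir results/
codonusage simulate --out syn.fasta --truth truth.json --seed 1
codonusage recover --truth truth.json --rundir results/
```

`run` writes per-gene profile and RSCU tables, force-attribution
tables, PCA outputs, correlation reports, the resolved configuration and
a checksummed manifest; reruns are byte-identical.

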