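# dietexpr

Analysis toolkit for diet-induced transcription in factorial bulk RNA-seq
designs — three diets (control **C**, dietary restriction **DR**, high sugar
**HS**) crossed with three tissues (body, head, ovary) and replicate
batches, as used for outbred *Drosophila* panels derived from the DSPR
multiparent population. The package covers the full analysis chain on such
a design and ships a synthetic-data generator that plants every quantity
the pipeline estimates, so each stage is testable without any sequencing
data.

## What it computes

**Differential expression.** Per-gene negative-binomial GLMs (log link,
log-size-factor offsets, method-of-moments dispersion with a floor) over a
nested model hierarchy

```
1: SV + batch + tissue
2: SV + batch + treatment
3: SV + batch + tissue + treatment
4: SV + batch + tissue + treatment + tissue:treatment
```

with likelihood-ratio tests for the tissue main effect (3 vs 2), the diet
main effect (3 vs 1) and the diet×tissue interaction (4 vs 3), adjusted by
Benjamini–Hochberg. Fold changes are moderated group-mean ratios,
log2((μ̂_A + c)/(μ̂_B + c)), computed within tissue for every diet pair
against every reference.

**Shared-reference concordance.** Two fold-change vectors computed against
the same reference diet correlate positively even for random data, because
they share the reference group's sampling noise. The package quantifies
observed concordance — Pearson *r* and the proportion of genes trending in
the same direction, (up in both + down in both)/total — and tests it
against a constrained permutation null: each pseudo-diet draws an equal
number of samples from every true diet, destroying the diet effect while
keeping composition balanced. Empirical p-values use the add-one rule
p = (1 + #{null ≥ observed})/(1 + M).

**Co-expression modules.** Signed weighted network
a_ij = ((1 + cor_ij)/2)^β, topological overlap, average-linkage clustering
with a static height cut, module eigengenes (first PC of the standardized
module submatrix), iterative merging of modules with eigengene correlation
above a threshold, replicate-resampling membership support (4-of-6 draws,
10% module-match / 50% gene-support rules), and per-module two-way
eigengene ANOVA (diet, tissue, interaction).

**Set-level statistics.** Welch two-sample t of per-gene fold changes in a
set versus the background (BH-adjusted) and one-sided Fisher exact
over-representation of module genes (Bonferroni-adjusted), over GMT
collections.

## Worked example

```python
import dietexpr as dx

cfg = dx.SimConfig(n_genes=1000, tissues=("B",), pi_de=0.3,
                   rho_concord=0.9, seed=42)
counts, meta, truth = dx.simulate_counts(cfg)
counts = dx.filter_low_counts(counts)           # 808 genes remain

de = dx.DifferentialExpression(counts, meta).fit()
print(de.summary())

conc = dx.ConcordanceTest(counts, meta, "B",
                          dx.PermutationScheme(100, 2, seed=0)).fit()
print(conc.summary().round(3))
```

prints

```
      contrast  n_tested  n_significant  fdr
treatment-main       808            182 0.05
tissue reference     pair     r  prop_same  p_emp_r  p_emp_prop   M
     B         C DR vs HS 0.433      0.705    0.950       0.030 100
     B        DR  C vs HS 0.610      0.666    0.010       0.465 100
     B        HS  C vs DR 0.451      0.629    0.871       0.990 100
```

182 of 808 genes test significant for the diet main effect at FDR 0.05
(30% carry planted effects). With C as the shared reference, 70.5% of genes
move in the same direction under DR and HS — significantly more than the
constrained permutation null (empirical p = 0.03), which itself centers
near 66%, not 50%: that excess-over-null, not the raw proportion, is the
evidence of a genuinely concordant diet response (here planted at
rho_concord = 0.9).

A command-line interface mirrors the library
(`dietexpr simulate | preprocess | de | concordance | modules | genesets | all`);
run `dietexpr --help`.

## Acceptance script

`scripts/acceptance.py` regenerates the package's headline simulation
quantity from scratch: it simulates a null dataset (3000 genes, 18
samples, no diet effect), runs 100 constrained permutations, and reports
the mean proportion of genes whose fold changes against a shared reference
trend in the same direction, as a percentage:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.
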