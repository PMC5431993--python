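# sysgen

A systems-genetics pipeline that walks genome-wide association signals
through tissue coexpression networks to a short list of candidate
causal genes — the analysis style used to dissect complex metabolic
traits such as obesity in human adipose tissue.

The pipeline has three stages:

1. **Discovery.** SNP-level GWAS summary statistics are collapsed to
   gene-wide p-values (minimum p over LD proxy clusters within the
   transcript + 1 kb promoter window); the nominally significant genes
   (p ≤ 0.05) seed a weighted gene coexpression network with soft-
   threshold adjacency *a<sub>ij</sub>* = |cor(*x<sub>i</sub>*,
   *x<sub>j</sub>*)|<sup>β</sup>, topological-overlap clustering into
   modules, module eigengenes (first principal components), and
   age-adjusted module–trait correlations. Hub genes have module
   membership kME > 0.8 and gene significance GS > 0.2, or maximal
   intramodular connectivity. The PC algorithm (Gaussian partial-
   correlation tests at α = 0.01) learns a causal graph over module
   genes and key driver analysis nominates regulators whose h-layer
   downstream neighborhood exceeds μ̄+σ and whose out-degree exceeds
   d̄+2σ. miRNAs predicted to target module genes are screened for
   significant negative expression correlation (BH FDR < 0.05).
2. **Replication.** Module preservation in independent datasets is
   quantified by permutation Zsummary (density + connectivity
   statistics; < 2 no evidence, ≥ 10 strong evidence), and module
   genes are meta-analyzed across studies by Fisher's method
   (χ² = −2Σln p on 2k df) and pooled Hedges-g standardized mean
   differences (fixed effects, or DerSimonian–Laird random effects
   when Cochran's Q has p < 0.05 or I² > 50%).
3. **Validation.** Per-dataset empirical-Bayes moderated t and
   moderated F contrast tests (time courses, group × time designs)
   with fold changes on the natural scale.

Because the real cohort data live behind controlled accessions, the
package ships a first-class synthetic-data generator
(`sysgen.simulate`) that plants the exact structure every stage is
meant to recover: latent-factor modules, a trait driven by one module's
eigengene plus age, a linear-SEM causal graph with a known root
regulator, anti-correlated target miRNAs, and replicate study
collections carrying a standardized group shift.

## Worked example

```python
from sysgen import CoexpressionNetwork, SimConfig, make_bundle
from sysgen.causal import PCAlgorithm

bundle = make_bundle(SimConfig(seed=7))          # 1000 genes, 200 samples
net = CoexpressionNetwork(beta=6).fit(bundle.expression)
print(net.labels_.value_counts().to_dict())

mt = net.module_trait_table(bundle.traits)
print(mt[mt.trait == "bmi"].round(3).to_string(index=False))

print(net.hub_genes(bundle.traits["obesity"], mode="max_connectivity"))

pc = PCAlgorithm(alpha=0.01).fit(bundle.causal_expression)
print(sorted(pc.key_drivers(list(bundle.causal_expression.index)).key_drivers))
```

prints

```
{'grey': 800, 'blue': 40, 'yellow': 40, 'green': 40, 'brown': 40, 'turquoise': 40}
   module trait      r     p    r2
     blue   bmi  0.573 0.000 0.328
    brown   bmi  0.016 0.828 0.000
    green   bmi  0.037 0.607 0.001
turquoise   bmi -0.052 0.467 0.003
   yellow   bmi -0.001 0.987 0.000
hubs: {'blue': ['G0000'], 'brown': ['G0120'], 'green': ['G0080'], 'turquoise': ['G0160'], 'yellow': ['G0040']}
key drivers: ['R']
```

All five planted 40-gene modules are recovered exactly (800 background
genes stay grey). The blue module is the planted trait module: its
eigengene explains 32.8% of BMI variation after age adjustment while
the other four modules are null. Its planted hub gene (G0000, the
highest-loading member) is returned as the maximum-connectivity hub,
and the planted root regulator R of the causal fixture is the sole key
driver.

The same stages run from the shell:

```bash
sysgen simulate --seed 7 --out bundle/
sysgen gwas --snps bundle/gwas_snps.tsv --genes bundle/gene_models.tsv \
            --ld bundle/ld.tsv --out out/
sysgen network --expr bundle/expression.tsv --traits bundle/traits.tsv \
               --beta 6 --out out/
sysgen preserve --ref bundle/expression.tsv \
                --test bundle/studies/study_1_expr.tsv \
                --modules out/modules.tsv --nperm 100 --seed 7 --out out/
```

or end to end with `sysgen run --config pipeline.yaml`.

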