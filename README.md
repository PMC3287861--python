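# genekm

Gene-based kernel machine association tests for quantitative traits,
with explicit support for gene-environment interaction and rare-variant
collapsing.

A gene's SNPs (minor-allele counts 0/1/2) enter a semiparametric model
`y = Xβ + h(input) + e`, where the nonparametric genotype effect `h` is
governed by a kernel. Testing `h = 0` reduces to a variance-component
score test in the equivalent mixed model: the statistic
`Q = r'Kr / (2σ̂²)` is a quadratic form in the null OLS residuals, whose
null distribution (a weighted sum of χ²₁ variables) is approximated by
Satterthwaite two-moment matching, with an exact Monte-Carlo oracle for
validation.

Six model formulations are provided:

| id  | fixed effects              | kernel input                    |
|-----|----------------------------|---------------------------------|
| M2  | covariates                 | per-SNP genotypes `g`           |
| M10 | covariates                 | collapsed burden `c = Σ g`      |
| M11 | covariates + `g`           | products `g·s` (interaction only) |
| M12 | covariates + `c`           | product `c·s` (interaction only)  |
| M13 | covariates                 | joint `[g | s | g·s]`           |
| M14 | covariates                 | joint `[c | s | c·s]`           |

where `s` is a binary exposure (smoking by default). Kernels: linear,
polynomial (quadratic default for the joint models), Gaussian, and an
allele-sharing (identity-in-state) similarity kernel. Population
stratification is adjusted by genotype principal components added to the
fixed effects.

A synthetic-data module generates workshop-style fixtures (~700
unrelated individuals, rare-variant genes, two latent subpopulations,
replicated phenotypes with exactly one gene-by-exposure interaction), so
all tests and analyses run without external data.

## Library quick start

```python
import genekm as gk

rs = gk.simulate(gk.default_config(seed=1))          # synthetic fixture
model = gk.ModelSpec("M12", kernel=gk.KernelSpec("polynomial", degree=2))
result = gk.run_scan(rs, [model])                    # genes x replicates
power = gk.empirical_power(result, alpha=0.05, truth=rs.truth)
qq = gk.qq_data(result.pvalues("GXE1", "M12"))       # with 95% null band
```

Single tests: `gk.test_gene(y, model, G, covariates, G_wide)` returns a
`ScoreTestResult` (Q, Satterthwaite scale/df, p-value).

## Command line

```sh
genekm simulate --config sim.json --out fixture/ --seed 1
genekm scan --genotypes fixture/genotypes.tsv --covariates fixture/covariates.tsv \
    --genemap fixture/genemap.tsv --phenotypes fixture/phenotypes.tsv \
    --model M12 --kernel quadratic --n-pcs 15 --out results.tsv
genekm qq --results results.tsv --gene GXE1 --model M12 --out qq.tsv
genekm power --results results.tsv --alpha 0.05 \
    --truth fixture/sim_meta.json --out power.tsv
```

All interchange formats are plain TSV with header rows (genotypes:
samples x SNPs; gene map: gene_id/snp_id pairs; covariates: Sex, Age,
Smoking; phenotypes: one column per replicate) plus a JSON sidecar for
simulation configs and truth labels.

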