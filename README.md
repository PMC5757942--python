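# pleiomap

Pleiotropy analysis of GWAS summary statistics. Starting from nothing but a
matrix of per-SNP association p-values (rows = SNPs, columns = phenotypes),
`pleiomap`:

1. **tests every phenotype pair for pleiotropy** with a four-group
   Beta-Uniform mixture model fitted by EM and a likelihood-ratio test
   against the factorized independence null (chi-square, 1 df);
2. **draws a phenotype map**: the pairwise test p-values are treated as
   distances, passed through a Box-Cox transform with a user-chosen zoom
   parameter `lambda`, min-max normalized, and embedded in 2-D by isomap
   (epsilon-neighborhood graph, Floyd-Warshall geodesics, classical MDS);
3. **clusters** the embedded coordinates (k-means or hierarchical);
4. **maps jointly associated SNPs** for any pair at a global FDR level via
   the local FDR `1 - Pr(shared | p1, p2)` and the cumulative-mean rule;
5. ships a **simulator** of the whole generative model (Uniform nulls,
   `Beta(alpha, 1)` signals, designated trait pairs with extra overlap
   beyond chance) so every stage is testable with no external data.

## CLI

```bash
# synthetic five-phenotype benchmark (presets A-D) -> p-value matrix TSV
pleiomap simulate --preset A --n-snps 20000 --seed 1 --out sim/

# all-pairs pleiotropy test matrix
pleiomap fit -i sim/sim_pvalues.tsv --out fit/

# transform + isomap + clustering + plot from a fitted matrix
pleiomap map -i fit/pleiotropy_pvalues.tsv --lam 0 --n-clusters 3 --out map/

# shared-SNP table for one pair at a global FDR level
pleiomap assoc -i sim/sim_pvalues.tsv --pair GWAS_1 GWAS_2 --fdr 0.05 \
    --out assoc.csv

# everything in one run (flags override an optional --config TOML)
pleiomap all -i sim/sim_pvalues.tsv --n-clusters 3 \
    --assoc-pair GWAS_1,GWAS_2 --seed 1 --out run/
```

`pleiomap all` writes the pleiotropy matrix (TSV), per-pair fit records
(JSON), embedded coordinates with cluster labels (TSV), assoc tables (CSV),
a run manifest (JSON), and the map as PDF + PNG. Omitting `--epsilon`
selects the smallest grid value whose neighborhood graph is connected.

## Python API

```python
import pleiomap as pm
from pleiomap.io import PValueMatrix, PipelineConfig, run_pipeline

sim = pm.simulate_scenario(pm.scenario_preset("A", n_snps=20_000, seed=1))
result = run_pipeline(PValueMatrix.from_frame(sim.pvalues),
                      PipelineConfig(lam=0.0, n_clusters=3, seed=1),
                      outdir="run")
result.pleiotropy.pvalues   # K x K symmetric LRT p-values
result.phenomap.coords      # K x 2 isomap coordinates
result.clusters.labels      # cluster labels, 1-based
```

Lower-level pieces (`fit_pair_em`, `lrt_pleiotropy`, `box_cox`,
`classical_mds`, `joint_assoc`, ...) are exported from the top-level
package.

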