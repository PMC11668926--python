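# asvkit

Ecology of abundant vs. rare taxa from ASV count tables: abundance-class
partitioning, alpha/beta diversity, distance-decay and ANOSIM, Spearman
co-occurrence networks with Erdős–Rényi nulls and keystone/O-R statistics,
βNTI + Raup–Crick (Bray–Curtis) assembly-process inference, and
environmental attribution (Mantel, partial Mantel, variance partitioning) —
plus a synthetic community generator with plantable assembly regimes,
abundance-class structure, spatial gradients and co-occurrence modules.

## Layout

| module | contents |
| --- | --- |
| `asvkit.core_io` | `AsvTable` / metadata / distance-matrix model, TSV + BIOM-JSON + newick readers, rarefaction, Good's coverage |
| `asvkit.partition` | six-way AAT/CAT/CRAT/MT/CRT/ART classification, sub-tables, summaries |
| `asvkit.diversity` | Chao1, Shannon, Faith PD, Bray–Curtis, unweighted UniFrac |
| `asvkit.spatial` | distance-decay regression, global/pairwise ANOSIM (permutation tests) |
| `asvkit.cooccurrence` | prevalence filter, Spearman edge network, node topology, keystones, G(n,m) null ensembles, degree-distribution fits, O/R ratios |
| `asvkit.assembly` | βMNTD/βNTI, RC-bray, five-way ecological-process classification |
| `asvkit.envstats` | Mantel / partial Mantel, single-factor environmental distances, two-set VPA via RDA, Wilcoxon rank-sum, Kruskal–Wallis |
| `asvkit.synthetic` | Yule trees, Brownian niches, regime presets (`generate_regime`), planted modules, exact partition fixtures |
| `asvkit.pipeline` | YAML-configured end-to-end run with manifest |

## CLI

```bash
# simulate a dataset (counts.tsv, tree.nwk, metadata.csv, truth.tsv)
asvkit simulate --seed 1 --out sim/

# abundance-class partition
asvkit partition --table sim/counts.tsv --rare-cut 1e-4 --abundant-cut 1e-2 --out part.tsv

# alpha/beta diversity
asvkit diversity --table sim/counts.tsv --tree sim/tree.nwk --out-prefix div

# distance-decay + ANOSIM on a beta matrix
asvkit decay --beta div_bray.tsv --metadata sim/metadata.csv --group season

# co-occurrence network
asvkit network --table sim/counts.tsv --rho-min 0.8 --alpha 0.01 --prevalence 0.2 --out-prefix net

# assembly processes
asvkit assembly --table sim/counts.tsv --tree sim/tree.nwk --nulls 999 --seed 1 --out assembly.tsv

# Mantel / partial Mantel
asvkit envstats mantel --beta div_bray.tsv --metadata sim/metadata.csv --factor TOC --perm 9999

# full pipeline from YAML
asvkit pipeline run --config run.yaml --seed 1
```

A pipeline YAML holds either input paths (`table_path`, `tree_path`,
`metadata_path`) or a `simulation:` block with `asvkit.synthetic.SimulationConfig`
fields, plus thresholds and replicate counts (see `asvkit.pipeline.PipelineConfig`).

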