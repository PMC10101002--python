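# fermnet

Co-occurrence networks, keystone taxa, and community-assembly statistics
for paired bacterial/fungal microbiome surveys of solid-state fermentations
(and similar multi-domain amplicon studies).

Spontaneous fermentations such as strong-flavor Baijiu are driven by a
mixed community of bacteria and fungi sampled over time from repeated
fermentation units.  Two kinds of taxa matter for the product: **dominant
taxa** (high relative abundance) and **keystone taxa** (highly connected
nodes of the co-occurrence network, often rare).  `fermnet` implements the
analysis chain that identifies both and asks how their communities
assemble:

- **Co-occurrence network** — pairwise Spearman correlations between taxa
  across samples; edges kept when |ρ| ≥ 0.8 and the Benjamini–Hochberg
  adjusted two-sided p ≤ 0.01.  Modules ("ecological clusters") by greedy
  modularity, Louvain, and fast label propagation, keeping the partition
  with the highest Newman–Girvan modularity Q.
- **Keystone classification** — within-module connectivity
  Z<sub>i</sub> = (k<sub>i,within</sub> − mean k<sub>within</sub>) / sd and
  among-module connectivity (participation)
  P<sub>i</sub> = 1 − Σ<sub>s</sub>(k<sub>is</sub>/k<sub>i</sub>)².
  Network hubs (Z ≥ 2.5, P ≥ 0.62), module hubs (Z ≥ 2.5), connectors
  (P ≥ 0.62); their union is the keystone set.
- **Robustness** — network stability as the proportion of species remaining
  after random node removal (200 replicates over removal ratios 0.5 %–100 %)
  with iterated secondary extinction of disconnected nodes.
- **Module function** — per-sample Shannon diversity (SDI) and z-scored
  abundance of each module, regressed against metabolite concentrations
  (e.g. ethyl acetate and the higher alcohols) with BH control.
- **Neutral model** — Sloan's neutral community model: the detection
  frequency of a taxon with metacommunity abundance *p* in samples of size
  *N* is `1 − BetaCDF(1/N; Nmp, Nm(1−p))`; the immigration rate *m* is fit
  by least squares, and taxa are partitioned neutral / above / below the
  95 % band.
- **NST** — the normalized stochasticity ratio against a
  proportional-proportional null model (richness and depth preserved;
  occurrence ∝ frequency, abundance ∝ mean relative abundance), with 50 %
  as the deterministic/stochastic boundary.
- **Indicator metabolites** — random-forest group discrimination with
  permutation importance (mean decrease in accuracy) and an rfcv-style
  10-fold cross-validation curve; the selected panel size is the smallest
  k within one standard error of the curve's minimum.
- **Synthetic data** — a generator producing paired bacterial/fungal count
  tables with planted ground truth: neutral background taxa with known
  *m*, environment-selected taxa, block-correlated module taxa with
  designated connector nodes, and metabolites linearly coupled to module
  diversity.  Every pipeline stage is benchmarked against this truth.

## Worked example

```python
import fermnet as fn

ds = fn.generate_dataset(seed=7)                     # planted ground truth
t = fn.filter_taxa(fn.merge_domains(ds.bacteria, ds.fungi))
net = fn.detect_modules(fn.build_network(t), seed=0)
roles = fn.zi_pi(net)
ks = fn.keystone_set(roles)
report = fn.truth_report(ds.truth, {"partition": net.partition,
                                    "connectors": ks.connectors})
print(f"nodes={len(net.nodes)} edges={net.n_edges} Q={net.modularity:.3f}")
print(f"connectors found: {sorted(ks.connectors)}")
print(f"module ARI={report['module_ari']:.2f} "
      f"connector recall={report['connector']['recall']:.2f}")

fit = fn.fit_neutral_model(ds.bacteria, n_boot=200, seed=0)
print(f"m={fit.m:.3f} R2={fit.r2:.3f} "
      f"neutral={fit.summary['neutral']['fraction_taxa']:.1%}")
```

prints

```
nodes=409 edges=465 Q=0.650
connectors found: ['b_otu60', 'b_otu61', 'b_otu62']
module ARI=1.00 connector recall=1.00
m=0.151 R2=0.966 neutral=60.9%
```

The network recovers the five planted modules exactly (adjusted Rand index
1.0) and classifies all three planted connector taxa as connectors
(P<sub>i</sub> ≥ 0.62).  The fitted immigration rate sits near the
generator's true value (*m* = 0.1; the mild upward bias is inherent to
fitting occurrence frequencies against abundances that are themselves
estimated).  Only ~61 % of the bacterial taxa fall inside the neutral band
here because this dataset deliberately plants non-neutral taxa — module
members, connectors, and environment-selected taxa — which the partition
correctly pushes outside the band; a purely neutral simulation partitions
~78 % neutral (see `scripts/acceptance.py`).

The same stages are available from the shell via the `ferment` command
(`ferment simulate`, `ferment network`, `ferment keystone`,
`ferment neutral`, `ferment nst`, `ferment indicators`, `ferment run`, ...);
run `ferment --help` for the full list.

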