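# plankton-assembly

Quantitative ecology of lake plankton communities from denoised amplicon
(ASV) tables: who assembles these communities — selection, dispersal, or
drift — and how does that balance shift across sampling months and trophic
state?

The package is aimed at microbial ecologists working with paired 16S
(bacteria) / 18S (eukaryote) ASV tables, a rooted phylogeny, and per-sample
physicochemistry from lake or reservoir surveys. It implements, as one
tested pipeline:

* **Beta-diversity decomposition** — Bray–Curtis dissimilarity D split
  exactly into species replacement and richness/abundance difference
  (Podani-family quantitative form), so each sample pair yields a ternary
  triplet S + Repl + RichDiff = 1.
* **Null-model assembly partitioning** — βNTI (z-score of abundance-
  weighted βMNTD against a taxa-shuffle null) and Bray–Curtis Raup–Crick
  (RC_bray), classified into homogeneous selection (βNTI < −2), variable
  selection (βNTI > 2), dispersal limitation (|βNTI| < 2, RC > 0.95),
  homogenizing dispersal (|βNTI| < 2, RC < −0.95) and undominated, with
  per-group process fractions and the sorting : dispersal ratio.
* **Sloan neutral community model** — occurrence frequency vs mean relative
  abundance, F(p) = 1 − I_d(Nmp, Nm(1−p)); fitted Nm, migration rate
  m = Nm/N, R², and a 95% envelope partitioning taxa.
* **Levins' niche breadth** — B_j = 1/Σ_i P_ij² and community-level Bcom.
* **Mantel correlograms** of phylogenetic niche signal, **distance-decay
  relationships** (similarity vs haversine km), **co-occurrence networks**
  (prevalence > 50%, Spearman |ρ| > 0.6, p < 0.01, betweenness-ranked core
  nodes, multi-domain merging), the **trophic lake index** (Chl-α, TN, TP,
  COD with correlation-derived weights; bloom flag at Chl-α > 40 μg/L) and
  **environmental heterogeneity** with permutation tests.
* A **synthetic-data generator** producing communities under known regimes
  (neutral migration, Gaussian environmental filtering of Brownian traits,
  spatially clustered drifted pools) so every estimator can be verified
  against ground truth.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

Simulate a dispersal-limited scenario (18 samples in 3 distant spatial
clusters, 500 taxa, 5000 reads/sample), then run the assembly chain:

```bash
plankton-assembly simulate --regime dispersal_limited \
    --n-samples 18 --n-taxa 500 --library-size 5000 --seed 7 --outdir sim
```

```python
import plankton_assembly as pa

table = pa.read_community_table("sim/counts.tsv")
tree = pa.simulate_tree(500, seed=99)          # any rooted Newick works
table = pa.CommunityTable(table.counts.set_axis(tree.tip_labels, axis=1))
meta = pa.read_metadata("sim/metadata.tsv")

at = pa.assembly_table(table, tree, n_null=199, seed=7)
at["g"] = "June"
print(pa.process_fractions(at, group_col="g").table)

fit = pa.fit_sloan_model(table)
print(f"Sloan fit: m = {fit.m:.4f}, Nm = {fit.Nm:.0f}, "
      f"R2 = {fit.r_squared:.3f}")

dd = pa.distance_decay(
    pa.similarity_from(pa.bray_curtis_matrix(table)),
    pa.geographic_distance(meta), n_perm=999, seed=7)
print(f"DDR: slope = {dd.slope:.2e} per km, R2 = {dd.r_squared:.3f}, "
      f"Mantel r = {dd.mantel_r:.3f} (p = {dd.mantel_p:.3f})")
```

Output:

```
 dispersal_limitation  homogenizing_dispersal  undominated  deterministic  stochastic
                69.93                   28.10          0.0           1.96       98.04
Sloan fit: m = 0.0291, Nm = 145, R2 = 0.373
DDR: slope = -2.16e-03 per km, R2 = 0.691, Mantel r = -0.831 (p = 0.001)
```

Read: 98% of pairs assemble stochastically; the modal process is dispersal
limitation (pairs between spatial clusters diverge more than the
randomization null expects, RC → +1) with homogenizing dispersal among
within-cluster near-replicates (RC → −1) — exactly the generating regime.
Community similarity decays with distance (negative DDR slope, Mantel
p = 0.001). The low neutral-fit R² reflects the non-neutral spatial
structure.

The trophic side works off the environment table alone:

```python
res = pa.compute_tli(pa.read_env_table("sim/env.tsv"))
```

```
      TLI             class  bloom
S1  60.36  middle eutrophic  False
S4  75.47    hypereutrophic   True
```

The same stages are available as CLI subcommands (`simulate`, `tli`,
`heterogeneity`, `betadiv`, `decompose`, `ddr`, `correlogram`, `assembly`,
`neutral`, `niche`, `network`), and `plankton-assembly run --config
config.yaml` executes the whole per-group pipeline with a single master
seed and per-stage derived seeds.

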