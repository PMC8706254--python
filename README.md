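# phyloassembly

Community-assembly inference for microbial (e.g. soil-fungal ITS) OTU
tables: who shaped the community — selection, dispersal, or drift?

`phyloassembly` implements the null-model toolkit used to answer that
question in survey designs such as altitudinal soil transects, where an
OTU count table, a rooted phylogeny and per-sample metadata (elevation,
soil layer, coordinates, soil chemistry) are available:

- **Phylogenetic null models.** NTI per sample and βNTI per sample pair,
  the (sign-flipped / plain) standardized effect sizes of MNTD and βMNTD
  against tip-label-shuffling ("taxa.labels") nulls:
  βNTI = (βMNTD_obs − mean_null) / sd_null. |βNTI| > 2 signals
  deterministic assembly (variable selection above +2, homogeneous
  selection below −2).
- **Raup–Crick on Bray–Curtis (RC_bray).** Probabilistic re-assembly
  nulls preserving each sample's richness and read total (occupancy-
  weighted draws, abundance-proportional reads); RC_bray ∈ [−1, 1]
  rescales the fraction of null pairs less dissimilar than observed.
- **Five-process partition.** Each sample pair becomes variable
  selection, homogeneous selection, dispersal limitation (RC > 0.95),
  homogenizing dispersal (RC < −0.95) or undominated/drift, with
  per-group percentage summaries (e.g. per soil layer).
- **Sloan's neutral community model.** Occurrence frequency vs mean
  relative abundance, f̂_i(m) from the Beta(N·m·p_i, N·m·(1−p_i))
  stationary distribution; migration rate m by bounded least squares,
  generalized R² = 1 − SS_res/SS_tot, and the above/neutral/below
  partition at the 95% band. Fits per group (e.g. per layer) compare
  migration rates across strata.
- **Species-abundance distributions.** Preston octave binning and the
  log-normal fit S(R) = S₀·e^(−a²R²) with a geometric-series comparator
  under AIC.
- **Diversity and correlations.** SR/Chao1/ACE/Shannon/Simpson/Faith PD,
  Bray–Curtis, weighted UniFrac, βMNTD; Mantel and partial Mantel tests
  against standardized-Euclidean environmental and haversine geographic
  distances.
- **Synthetic data with ground truth.** Yule trees, log-normal
  metacommunities, and count tables under known regimes — neutral
  (Dirichlet-multinomial), phylogenetically structured selection
  (Brownian trait + Gaussian niche), and patch-limited dispersal — so
  every stage of the pipeline can be validated against the regime that
  generated its input.

## Worked example

Fit Sloan's neutral model to a neutrally assembled community with a
known migration rate (`examples/02_sloan_neutral_model.py`):

```python
from phyloassembly import fit_ncm, simulate_scenario

scen = simulate_scenario("neutral", seed=8, n_taxa=500, n_samples=40, reads=2000)
fit = fit_ncm(scen.table)
```

prints

```
migration rate m = 0.495 (true value 0.5)
generalized R^2  = 0.982  (> 0.2 reads as a neutral signal)
community size N = 2000 reads, detection threshold d = 5.00e-04
OTUs vs the 95% neutral band: {'above': 56, 'neutral': 383, 'below': 5}

Preston log-normal fit: S0 = 59.5 species at the modal octave, a = 0.230 (width 1/a = 4.35 octaves)
AIC log-normal 66.5 vs geometric 88.3 -> log-normal preferred
```

The simulated community has true m = Nm/N = 1000/2000 = 0.5; the fit
recovers it to 1%, the high R² correctly flags neutral assembly, and the
log-normal SAD — the form the metacommunity was drawn from — wins the
AIC comparison. The other example scripts partition assembly processes
on a dispersal-limited landscape (`examples/01_…`) and run
distance-decay Mantel tests under environmental selection
(`examples/03_…`).

The same pipeline runs end to end from a shell:

```bash
phyloassembly simulate --regime dispersal_limited --n-taxa 400 --n-samples 16 \
    --reads 1000 --seed 4 --out sim/
phyloassembly partition --table sim/table.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --group-column group --out results/
```

or from one YAML config via `phyloassembly run --config pipeline.yaml`,
which executes align → alpha → beta → null models → partition → NCM/SAD
→ Mantel with a single global seed and byte-reproducible outputs.

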