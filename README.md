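# edgeclust

Deconvolution of subcellular protrusion heterogeneity from live-cell
time-series data, for quantitative cell biologists studying leading-edge
dynamics and actin regulation.

Cell protrusion is driven by actin polymerization machinery whose regulators
(Arp2/3, VASP, actin itself) are recruited with distinct timing. Bulk
averaging of edge velocity hides this heterogeneity: different subcellular
regions of the same cell protrude with different temporal programs.
`edgeclust` takes per-window maps of edge velocity (nm/s, sampled in ~500 nm
probing windows every 5 s) and matched fluorescence intensities, registers
significant protrusion events at their onsets, and deconvolves them into
phenotypic clusters that can then be linked statistically to regulator
recruitment dynamics and drug responses.

## Method

The clustering core works on onset-registered, 56-frame velocity series
(5 pre-onset + 51 post-onset frames):

1. **Event registration** — velocity is integrated to edge displacement,
   smoothed with a cubic smoothing spline (p = 0.01); protrusion events are
   minimum-to-maximum excursions after discarding events with net distance
   < 720 nm and merging protrusion/retraction switches shorter than 50 s.
2. **EMD denoising** — displacement is decomposed into intrinsic mode
   functions; components whose detrended-fluctuation-analysis exponent α
   falls below 0.33 are treated as noise and removed.
3. **SAX symbolization** — each series is reduced to an N = 16 symbol word
   over an M = 4 alphabet, with breakpoints at the equiprobable quantiles of
   a Gaussian fitted to the pooled values.
4. **ACF dissimilarity** — the distance between two series X, Y is
   `d²_ACF(X,Y) = Σᵢ (ACF(X)ᵢ − ACF(Y)ᵢ)²` over lags 1…15 of the symbol
   sequences, grouping series by temporal pattern rather than amplitude or
   phase.
5. **Density-peak clustering** — each sample gets a local density
   `ρᵢ = Σ_{k≠i} exp(−(d_ik/dc)²)` and a separation δᵢ (distance to the
   nearest denser sample); cluster centers score high on both, and every
   other sample inherits the label of its nearest denser neighbour.

Downstream analyses: time-lag and time-specific (t₁,t₂) Pearson correlation
of velocity with regulator intensity (bootstrap CIs, Benjamini–Hochberg FDR),
binary classification of accelerating vs non-accelerating protrusions from
intensity series (random forest / SVM / neural network, with undersampling
and MCC reporting), pooled control/treatment clustering with a cell-level
bootstrap test of cluster proportions, and spatial co-occurrence of
phenotypes along the edge.

No public dataset accompanies the window maps this pipeline consumes, so
`edgeclust.synthetic` generates registered velocity sets from five phenotype
templates (fluctuating plateau; periodic with 1–3 velocity peaks;
accelerating ramp), intensity channels coupled to velocity with configurable
lag/sign/noise, raw window maps with injected events, and per-cell cluster
count tables — all with known ground truth and bit-reproducible under a seed.

## Worked example

```sh
edgeclust simulate --n-per-cluster 20 --noise 2 --lag 2 --seed 1 --out sim
edgeclust run --velocity sim/velocity.csv --intensity sim/intensity.csv --out res
```

prints

```
wrote 100 series to sim
{"k": 5, "dc": 0.1591625091921495, "n_samples": 100, "lag_argmax": 2}
```

The pipeline recovered `k = 5` phenotype clusters from the 100 simulated
series (the five generator templates), chose the density kernel radius
`dc ≈ 0.16` by grid search on the induced clustering quality, and the
time-lag correlation between velocity and the coupled intensity channel
peaks at `lag_argmax = 2` frames — the lag injected by `--lag 2`
(intensity trailing velocity by 10 s). Cluster labels are in
`res/labels.csv`, the ρ–δ decision graph in `res/…` via the `cluster`
subcommand, and every output directory carries a `config.json` with the
full parameter set.

The same functionality is available as a library:

```python
from edgeclust import synthetic, pipeline
vel, truth = synthetic.generate_velocity_set(100, noise_sd=2.0, seed=1)
out = pipeline.cluster_velocities(vel.matrix)   # out.labels, out.k, out.dc
```

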