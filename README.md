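# chromaburst

Spatial statistics and stochastic modeling of transcriptional co-bursting
on single chromosomes.

Chromatin tracing with sequential DNA FISH measures the 3D centroid
positions of hundreds of consecutive 50-kb segments on thousands of
individual chromosome copies, and nascent-RNA FISH scores each of ~80
genes on every copy as transcriptionally on (1) or off (0).  This package
implements the analysis chain that links those two measurements:

* **Spatial statistics** — median physical distance (MPD) and STD
  matrices conditioned on transcription state, promoter-centered metagene
  maps, promoter-to-local-centroid distances, state-conditioned
  promoter-pair distances, expected-MPD baselines, contact frequency
  (fraction of copies with r < 200 nm) and activity/density partitions.
* **Co-expression** — the ϕ coefficient (Pearson correlation of two
  binary state vectors, computed from the 2×2 contingency table

  ϕ = (n₁₁n₀₀ − n₁₀n₀₁) / √((n₁₁+n₁₀)(n₁₁+n₀₁)(n₀₀+n₁₀)(n₀₀+n₀₁)) )

  as a function of genomic distance, contact frequency, ensemble MPD and —
  the key observable — the single-chromosome distance between the two
  promoters (200-nm bins, ≥100 chromosome copies per pair and bin).
* **Live-cell dynamics** — relative motion of bursting alleles,
  time/ensemble-averaged MSD and an origin-constrained fit giving the
  single-allele diffusion coefficient (MSD = 2·d·D_eff·Δt, D = D_eff/2
  for relative tracks; default D_TFF1 = 2.5×10⁻⁴ μm²/s).
* **Distance process** — an overdamped Langevin model of the inter-gene
  distance, dr/dt = μ(r) + √(2D)·g(t), whose drift is derived from the
  measured steady-state distance distribution through the stationary
  Fokker–Planck balance μ(r) = D·d ln Pₛ/dr, after deconvolving the
  localization-error kernel (a noncentral-chi blur, σ = 100 nm per locus
  per axis) from the observed histogram.
* **Co-bursting model** — nascent-RNA production split into co-bursts and
  individual bursts with distance-dependent propensities
  P_ij = ω(r(t))·P_i^tot, P_i = P_i^tot − P_ij, P_j = P_j^tot − P_ij and
  per-molecule decay Pd = 1/800 s⁻¹; calibration of P^tot via a simulated
  lookup table of on-fraction vs propensity; the fit of the monotone
  non-increasing step function ω(r) by minimizing
  Σ_pairs Σ_bins |ϕ_sim(r) − ϕ_obs(r)|; and noise-removal experiments that
  re-simulate the fitted model without localization error, with
  deterministic 800-s on times, and without distance diffusion.
* **Synthetic data** — a freely-jointed-chain generator with planted
  coupling, dropout, localization error and Brownian allele tracks, so
  every estimator can be tested against known ground truth.

## Worked example

Fit the diffusion coefficient from simulated live-cell allele tracks:

```python
from chromaburst import dynamics, synthetic

cfg = synthetic.SyntheticConfig(n_chromosomes=0, n_loci=2, rng_seed=0)
trajs = synthetic.generate_allele_trajectories(cfg, n_cells=50,
                                               duration=3000.0, dt=10.0)
rel = dynamics.relative_positions(trajs)          # 50 allele pairs
curve = dynamics.msd(rel, max_lag=3000.0, seed=0)
print(dynamics.fit_diffusion(curve, n_dims=2, relative=True))
# 0.00026384... — the planted 2.5e-4 um^2/s within ~6%
```

The full analysis (synthetic study → spatial statistics → ϕ curves → MSD →
distance model → ω fit → noise removal) is laid out as numbered scripts:

```
python analysis/01_simulate_data.py
python analysis/02_spatial_structure.py
...
python analysis/07_noise_removal.py
```

Each script prints what it found and writes its tables under `results/`.
On the default study (3,000 chromosomes, three gene pairs with a planted
ω = 0.3 below 400 nm, 100-nm localization error) the scripts print, among
other things:

```
fitted single-allele D = 2.638e-04 um^2/s (planted 2.500e-04)
mean coupling below 400 nm: fitted 0.30, planted 0.30
first-bin ladder: [0.04  0.036 0.094 0.459]
```

i.e. the diffusion coefficient is recovered to ~6%, the short-range
coupling aggregate is recovered exactly even though individual 200-nm bins
below the smearing scale trade off against each other, and removing
measurement noise (localization error, stochastic on times, distance
diffusion) raises the first-bin correlation roughly tenfold — the
uncorrected/corrected contrast the model exists to quantify.

The same stages are available as a CLI (`chromaburst run-all --seed 0
--out out/`, or per-stage subcommands `simulate-data`, `spatial`,
`coexpr`, `msd`, `distance-model`, `coburst`) driven by a single YAML
config with hash-derived per-stage sub-seeds.

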