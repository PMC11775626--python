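# occudiel

Camera-trap analysis of **space use** and **diel activity overlap** for a
tiger–prey community: single-season site-occupancy models with imperfect
detection, a two-stage design feeding prey space-use estimates into the
predator model, circular-kernel activity-overlap inference, and
inverse-distance-weighted (IDW) mapping of the fitted space-use surface.
A fully specified synthetic-study generator with known ground truth stands
in for field data (real camera-trap presence data for threatened species
are typically withheld), so every stage of the pipeline is testable
against truth.

## Who this is for

Quantitative ecologists analysing detection/non-detection data from
trail-camera grids: estimating how much of a landscape a predator uses,
which prey and anthropogenic covariates drive that use, and how the
predator's daily activity rhythm overlaps with prey, humans and livestock.

## The models

**Occupancy / space use.** Each camera site *i* is used with probability
ψᵢ and, given use, the species is detected on each active occasion with
probability pᵢ, with logit-linear covariates on both:

    logit(ψᵢ) = xᵢ′β,   logit(pᵢ) = wᵢ′α
    Lᵢ = ψᵢ ∏ⱼ pᵢ^{yᵢⱼ} (1−pᵢ)^{1−yᵢⱼ}  +  (1−ψᵢ)·1[no detections at i]

(the product runs over camera-active occasions only). Fitting is by exact
maximum likelihood (`OccupancyModel.fit()`) or by a Metropolis-within-Gibbs
sampler (`OccupancyModel.sample()`; latent states drawn from their exact
full conditional, adaptive random-walk Metropolis on the coefficient
blocks; defaults 3 chains, 1000 adaptations, 1000 burn-in, 10 000 retained
iterations, convergence flagged at R̂ > 1.1). Summaries report posterior
mean, sd, equal-tailed 95% limits, rank-normalized split R̂, ESS and
`overlap0` — the indicator that the interval contains zero, the
significance rule used throughout.

**Two-stage design.** Prey species are fitted first with constant
detection; their per-site posterior-mean ψ fields then enter the tiger
model as standardized covariates, with tiger detection modelled on
distance to roads and water. Covariates are screened beforehand by
pairwise correlation (|r| > 0.7) and variance inflation (VIF > 5) with an
ecological keep-list. The fitted tiger ψ is projected onto a raster by
IDW (power 2).

**Diel overlap.** Detection clock times map to the circle
(t = 2π·s/86400). Activity densities are von Mises kernel density
estimates with a plug-in concentration rule; overlap between two species
is the coefficient of overlapping Δ = ∫ min(f̂, ĝ) ∈ [0, 1], estimated by
Dhat1 (grid quadrature, small samples) or Dhat4 (density ratios at the
observations, larger samples). Uncertainty comes from a 999-resample
smoothed bootstrap (norm0 intervals); significance from a randomization
test drawing both samples from the kernel density of the pooled data.

## Worked example

```python
import occudiel as od

cfg = od.default_config(seed=1)                    # 94 sites, 21 occasions
ds = od.SyntheticStudy(cfg).generate()
events = od.collapse_bursts(ds.records)
hist = od.build_history(events, "tiger", ds.effort)
print(f"{len(events)} detection events; tiger naive occupancy "
      f"{hist.naive_occupancy:.3f}")

model = od.OccupancyModel.from_history(
    hist, ds.covariates.set_index("site_id"),
    psi_columns=("forest_km2", "human_count"), p_columns=("dist_road",))
res = model.sample(chains=3, adapt=1000, burnin=1000, iterations=10000, seed=1)
print(res.summary().round(3)[["mean", "sd", "LCL", "UCL", "Rhat", "overlap0"]])

tiger, sambar = od.diel_sample(events, "tiger"), od.diel_sample(events, "sambar")
est = od.overlap(tiger, sambar)
ci = od.bootstrap_ci(tiger, sambar, n_boot=999, rng=1)
print(f"{est.estimator} = {est.dhat:.3f}, norm0 95% CI = "
      f"({ci.lower:.3f}, {ci.upper:.3f})")
```

prints

```
2742 detection events; tiger naive occupancy 0.585
                  mean     sd    LCL    UCL   Rhat  overlap0
parameter
psi              0.585  0.042  0.501  0.664  1.001         0
p                0.750  0.013  0.725  0.775  1.001         0
psi:(Intercept) -0.073  0.301 -0.686  0.501  1.001         1
psi:forest_km2   2.045  0.572  1.068  3.297  1.001         0
psi:human_count -1.635  0.739 -3.305 -0.411  1.003         0
p:(Intercept)    1.102  0.068  0.971  1.237  1.001         0
p:dist_road     -0.029  0.061 -0.146  0.094  1.001         1
Dhat4 = 0.709, norm0 95% CI = (0.664, 0.753)
```

Reading the table: the derived rows `psi` and `p` are the study-mean
space-use and detection probabilities (here 0.585 and 0.750 — detection is
high, so naive occupancy is close to ψ); coefficient rows are on the logit
scale for standardized covariates, and `overlap0 = 0` marks intervals
excluding zero. `Dhat4 = 0.709` says tiger and sambar share about 71% of
the area under their activity curves.

The same stages are scriptable from the shell: `occudiel simulate`,
`occudiel screen`, `occudiel fit`, `occudiel pipeline --config config.yaml`
(which writes `table1.csv`, `table2.csv`, `psi_sites.csv`, `psi_grid.asc`
and `report.json`), and `occudiel diel`.

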