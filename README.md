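# megconn

Phase-lag connectivity and network-level statistics for resting-state MEG
source time series — with a fully synthetic, ground-truth-bearing cohort
generator so the whole pipeline can be validated end to end.

## Who this is for

Researchers analysing source-reconstructed resting-state MEG (or any
region × time oscillatory data) in case–control cohorts — e.g. children born
very low birth weight (VLBW, < 1500 g) versus full-term controls — who want
to test for group differences or covariate-adjusted associations
(IQ, behaviour scores, early nutrient intake) at the level of connected
subnetworks rather than single connections.

## The method

1. **Preprocess**: 1–150 Hz zero-phase Butterworth band-pass + 60/120 Hz
   spectral notches; 10 s epochs; epochs dropped for head motion > 5 mm or
   amplitude beyond a limit; subjects kept with ≥ 6 epochs (1 min).
2. **Band-limited phase**: zero-phase two-pass FIR into theta (4–7 Hz),
   alpha (8–14), beta (15–29), low gamma (30–55) and gamma (65–80 Hz), then
   the Hilbert analytic signal.
3. **Connectivity**: the weighted phase lag index per epoch, averaged over
   epochs,

       wPLI(i, j) = |Σ_t Im X_t| / Σ_t |Im X_t|,   X_t = z_i(t) conj(z_j(t)),

   a 0–1 phase-synchronisation measure blind to instantaneous (volume-
   conduction) mixing — giving one symmetric region × region matrix per
   subject and band.
4. **Network-based statistic (NBS)**: each edge is z-scored across
   participants and fitted with an OLS GLM (intercept + predictor +
   covariates, default age at scan and sex); the observed direction-signed
   t map is thresholded at the quantile leaving ~1 % of edges (40 of 4005
   for 90 regions); connected components of the supra-threshold graph are
   scored by extent (edge count) against a permutation null of maximum
   extents (group-label permutation, or Freedman–Lane residual permutation
   under covariates), giving family-wise-error-corrected component p-values
   p_corr = (1 + #{null ≥ extent}) / (1 + N).
5. **Report**: node degrees and hubs, BrainNet Viewer `.node`/`.edge`
   export, demographics comparisons (chi-square / t / Mann-Whitney per
   Shapiro-Wilk), and postnatal day 9–29 nutrient-intake summaries with
   recommendation-achievement flags (protein 3.5, lipid 4.8, carbohydrate
   11.6 g/kg/day; energy 110 kcal/kg/day).

The synthetic generator plants phase-lagged couplings of strength κ per
group on chosen edges, so the pipeline's detection behaviour can be measured
against known truth. See `docs/methods.md` for the full model description.

## Worked example

```python
import megconn as mc

# a 10+10-subject cohort with a 6-edge alpha-band star network coupled at
# kappa = 0.8 in group A vs 0.3 in group B
spec = mc.SyntheticCohortSpec(
    n_group_a=10, n_group_b=10, n_regions=30, n_epochs=8,
    bands=("alpha",), planted_edges=tuple((0, k, "alpha") for k in range(1, 7)),
    coupling_a=0.8, coupling_b=0.3, noise_sd=0.5, seed=1,
)
cohort = mc.generate_cohort(spec)
mats = [
    mc.subject_connectivity(mc.band_analytic(s, mc.get_band("alpha")))
    for s in cohort.series
]
design = mc.DesignSpec(
    mode="group_contrast", predictor="group", contrast_level="A",
    covariates=("age_at_scan", "sex"), direction="positive",
    target_edge_fraction=0.01, n_permutations=500,
)
res = mc.NetworkBasedStatistic.from_matrices(mats, cohort.table, design).fit()
print(res.summary())
```

prints

```
Network-based statistic
============================================================
mode:            group_contrast
predictor:       group (positive direction)
covariates:      age_at_scan, sex
band:            alpha
subjects used:   20 (0 dropped, listwise)
GLM df:          16
primary t thresh: 22.7294 (target fraction 0.01)
permutations:    500
------------------------------------------------------------
 component  extent  n_nodes  p_corrected  significant
         0       4        5     0.001996         True
```

The planted group difference is recovered: the single significant component
(p_corr ≈ 0.002) is the top of the planted star — with a 1 % edge threshold
on 30 regions only 4 of 435 edges survive thresholding, and all 4 are
planted edges (edge Jaccard 4/6 ≈ 0.67 against the 6-edge ground truth).
Hubs and export:

```python
comp = res.significant_components()[0]
degrees = mc.node_degree(comp)   # {0: 4, 3: 1, 4: 1, 5: 1, 6: 1} — region 0 is the hub
```

The same analysis runs from the shell on a packaged demo configuration:

```bash
megconn pipeline --config src/megconn/data/demo_config.yaml --out results/demo
```

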