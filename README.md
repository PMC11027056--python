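# kpsae

Key-population size estimation with program-data priors and small-area
extrapolation.

HIV programs need to know how many female sex workers (FSW) and men who
have sex with men (MSM) live in each administrative region, but direct
population size estimates (PSEs) — from mapping, multiplier methods,
successive sampling PSE (SS-PSE), and similar bio-behavioral survey
methods — exist only for a handful of mostly urban regions, and the
methods frequently disagree within one region. `kpsae` implements a
pipeline, modelled on the estimation exercise carried out for Namibia's
13 regions, that

1. elicits a **log-normal prior** on population size from routinely
   collected program data (quarterly counts of people reached by HIV
   services, reported through DATIM- and KP-STAR-like systems);
2. **triangulates** the competing method-level estimates of each surveyed
   region into a single consensus estimate with a Bayesian
   precision-and-confidence-weighted combination on the log scale;
3. **extrapolates** to regions without survey data via small-area
   estimation: simple imputation, stratified imputation after a median
   split on HIV prevalence or population density, and a supplemental
   offset-Poisson regression clustered by region;
4. ships a **synthetic-data generator** with known ground truth so every
   stage is testable for parameter recovery without restricted data.

It is aimed at epidemiologists and HIV-program analysts who need
reproducible subnational PSEs from heterogeneous inputs.

## The model

Each direct estimate *i* for a region enters on the log scale as a
Gaussian observation of the true log size
μ: ln xᵢ ~ N(μ, σᵢ²), with σᵢ = (ln Uᵢ − ln Lᵢ)/(2·1.96) recovered from
its 95% CI. A method-confidence weight wᵢ ∈ (0, 1] (SS-PSE 1 down to
wisdom-of-the-crowds 1/7) tempers its precision, and the program-data
prior μ ~ N(μ₀, σ₀²) with μ₀ = ln(median), σ₀² = ln(1 + (sd/median)²)
enters as one more Gaussian term. The posterior is conjugate:

    σ⁻²_post = σ₀⁻² + Σᵢ wᵢ/σᵢ²
    μ_post   = σ²_post · (μ₀/σ₀² + Σᵢ wᵢ ln xᵢ/σᵢ²)

and the consensus estimate is exp(μ_post) with interval
exp(μ_post ± 1.96 σ_post). Consensus sizes are divided by survey-year
census denominators (ages 18–49) to give proportions, imputed to
off-sample regions (globally or per median-split stratum), and applied
to projected target-year populations (ages 15–49):
estimate = round(proportion × projection). The regression variant fits
log E[count] = β₀ + Σβⱼxⱼ + ln(denominator) by GEE with region clusters
and selects covariates by AIC/BIC.

## Worked example

Triangulate the bundled published direct estimates (four surveyed regions
per population; no prior, since the original program-count summaries were
never published):

```python
from kpsae.datasets import load_namibia_direct_estimates
from kpsae import consensus_by_group

cons = consensus_by_group(load_namibia_direct_estimates())
print(cons[["region_id", "population", "point", "ci_lower", "ci_upper", "n_inputs"]].round(0))
```

```
region_id population  point  ci_lower  ci_upper  n_inputs
   erongo        FSW  869.0     667.0    1132.0         7
   erongo        MSM  673.0     561.0     807.0         7
    karas        MSM  877.0     685.0    1122.0         6
   khomas        FSW 2131.0    1832.0    2478.0         7
   khomas        MSM 1640.0    1255.0    2143.0         7
ohangwena        FSW 1096.0     917.0    1310.0         7
   oshana        MSM  718.0     532.0     970.0         6
  zambezi        FSW 1224.0     880.0    1702.0         7
```

Each row is the precision- and confidence-weighted pooling of that
region's 6–7 method-level estimates: e.g. the 7 Khomas FSW estimates
(100 to 5240) collapse to 2131 (95% CI 1832–2478). Karas and Oshana MSM
pool 6 inputs because SS-PSE was never fielded there. (The published
consensus values are lower because they shrank toward program-data priors
whose inputs are not public.)

Run the full pipeline on a synthetic dataset with known truth:

```python
from kpsae.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(simulate={"seed": 7}, populations=("FSW",)))
print(bundle["national_summary"])
```

```
population            variant    data_mode  national_estimate
       FSW             simple  pre_program              20089
       FSW     stratified_hiv  pre_program              19714
       FSW stratified_density  pre_program              20413
       FSW             simple post_program              19226
       FSW     stratified_hiv post_program              19215
       FSW stratified_density post_program              19391
```

One national total per imputation variant and data mode: `pre_program`
averages all method-level proportions, `post_program` uses the
prior-informed consensus estimates. The same run is available from the
shell via `kp-sae run --config config.yaml --out results/`, plus
subcommands `priors`, `consensus`, `sensitivity`, `impute`, `regress`,
and `simulate`.

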