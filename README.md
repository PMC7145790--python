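# enwas

Ecological environment-wide association analysis for areal disease counts:
a staged small-area pipeline combining a frequentist exposure screen,
Bayesian disease mapping with a BYM2 spatial random effect, and a
multivariable spatial ecological regression. Built for epidemiologists and
biostatisticians working with district-level counts of a rare disease
(e.g. childhood type 1 diabetes) and many candidate environmental
covariates.

## The analysis

For areal units `i` with observed counts `O_i`, indirectly age–sex
standardised expected counts `E_i` (internal reference, so `ΣE = ΣO`), and
exposures `x`:

1. **EnWAS screen** — one univariable Poisson regression per exposure,
   `O_i ~ Poisson(E_i · exp(a + b·x_i))`, fitted by IRLS; Bonferroni
   control of the family-wise error over the m exposures (`p < α/m`);
   Manhattan (`−log10 p × sign`) and QQ quantities.
2. **Disease mapping** — the same model in a Bayesian framework with a
   BYM2 convolution effect `b_i = σ(√φ·u*_i + √(1−φ)·v_i)`, where `u*` is
   a scaled ICAR field on the area adjacency graph and `φ` is the
   structured share of random-effect variability. Outputs: smoothed
   relative risks `exp(b_i)`, 95% credible intervals, and 80% posterior
   exceedance classifications (elevated / lowered / uncertain).
3. **Selection + ecological regression** — covariates passing *both*
   screens (adjusted p < 0.05 and a CrI excluding 1) are clustered by
   |Spearman ρ| ≥ 0.7; one representative per cluster enters a
   multivariable BYM2 regression.

A synthetic-region generator (354 areas, 53 correlated exposures,
stratified populations, known β/σ/φ) makes every stage testable without
any external data. See `docs/methods.md` for models, priors, the MCMC
scheme and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic region and write tables, plots and JSON summaries under
`results/`:

```sh
python analysis/01_simulate_region.py
python analysis/02_standardize_incidence.py
python analysis/03_enwas_screen.py
python analysis/04_disease_mapping.py      # ~3 min: 1 + 53 spatial fits
python analysis/05_select_and_regress.py
```

Output of a run with the default seed:

```
areas: 354  exposures: 53
case counts: min 6  median 37  IQR 23-56  max 143  total 14967
truth: sigma=0.3  phi=0.78
incidence 22.2 (95% CI 21.8, 22.6) per 100,000
19 of 53 exposures pass the Bonferroni threshold p < 0.0009
null model fitted in 14s (converged: True)
smoothed RR range: 0.51 to 2.29
structured share of variability: 52% (95% CrI 23-84%)
areas with >=80% probability of elevated risk: 99/354; lowered: 106/354
9 variables pass both screens; 6 selected after correlation clustering
temporal-split Pearson correlation (period A vs B counts): 0.876
```

Reading the numbers: the incidence line is the overall rate per 100,000
person-years with its exact Poisson CI; the screen line counts exposures
whose Wald p clears 0.05/53; the mapping lines give the range of smoothed
area-level relative risks, the posterior share of random-effect
variability attributed to spatial structure, and the counts of areas
confidently above/below the national mean; the final lines show the
dual-screen selection and the stability of the spatial pattern across two
sub-periods.

Everything is also scriptable through the library (`import enwas`) or the
CLI (`enwas run --out results/run --seed 1`), which executes
simulate → standardize → screen → map → select → ecoreg and writes a
manifest with SHA-256 hashes of every artefact; a fixed seed reproduces
the outputs byte for byte.

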