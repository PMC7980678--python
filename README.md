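# promoscan

Household-level analysis of **price promotions on sugar-sweetened beverages
(SSBs)** from linked retail-scanner and consumer-panel data.

Retailers temporarily discount SSBs to incentivize purchasing. `promoscan`
quantifies each household's annual exposure to such discounts from weekly
store prices and estimates how strongly exposure is associated with how much
the household buys. Because the commercial scanner databases this kind of
study runs on are proprietary, the package ships a seeded synthetic
generator that reproduces their statistical structure with *planted* effect
sizes, so the whole pipeline is testable end to end.

## The model

For each store *s* and product *p*, the regular price is proxied by the
**modal price** m<sub>sp</sub> — the most frequently observed weekly unit
price over the year (ties broken to the highest tied price, since
promotions deflect prices downward). The weekly discount of product *p* is

    d_spw = max(0, (m_sp − price_spw) / m_sp)

Product discounts are combined into one store-week promotion magnitude by a
weighted mean, with weights proportional to each product's share of total
purchase volume in the household sample. A household's weekly exposure is
the **largest** such magnitude among the stores where it bought SSBs during
the year (sensitivity: the **average**). Annually,

    frequency = #(weeks with weekly magnitude ≥ 5%) / 52
    magnitude = mean of the 52 weekly magnitudes

The outcome is annual per-capita SSB purchase ounces (total household
ounces / household size), log-transformed. The association is estimated by
OLS:

    ln(annual_oz_i) = α + β·x_i + γ′z_i + ε_i

with x = frequency×10 or magnitude×100 and z the dummy-coded household
covariates (size, income per capita, head ages/educations/occupations,
children, race, region, urbanicity). exp(β) is the multiplicative change in
purchase volume per 10 percentage points of frequency (or 1 point of
magnitude); percent change = 100·(exp(β) − 1). Subgroup heterogeneity is
tested with exposure×modifier interaction terms and a Type-3 (partial F)
test of the interaction block.

## Worked example

```python
import promoscan as ps

dataset = ps.generate(ps.GeneratorConfig(seed=42))
linkage = ps.linkage_report(dataset["purchases"], dataset["stores"])
included = ps.apply_inclusion(linkage, 0.80)
derived = ps.compute_annual_exposure(dataset, ps.ExposureConfig(), households=included)
cohort = ps.build_cohort(dataset, derived["annual"], included)
print(f"analytic sample: {len(cohort)} of {len(linkage)} households")
print(f"mean annual promotion frequency: {cohort['frequency'].mean():.3f}")
print(f"mean annual promotion magnitude: {cohort['magnitude'].mean():.3f}")
res = ps.fit_main(cohort, ps.ModelSpec("frequency"))
print(f"exp estimate per 10 pp frequency: {res.exp_estimate:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
print(f"percent change: {ps.percent_change(res.exp_estimate)}%")
```

prints

```
analytic sample: 785 of 1000 households
mean annual promotion frequency: 0.373
mean annual promotion magnitude: 0.044
exp estimate per 10 pp frequency: 1.112 (95% CI 1.031-1.200)
percent change: 11.2%
```

i.e. households in this synthetic world saw an SSB discount in 37% of
weeks, prices averaged about 4.4% below the regular price, and each
additional 10 percentage points of promotion frequency is associated with
an 11.2% higher annual per-capita purchase volume — the confidence interval
covers the generator's planted effect of 1.137.

The same steps are available from a shell:

```sh
promoscan simulate --seed 42 --out data/
promoscan validate --data-dir data/
promoscan fit --data-dir data/ --exposure frequency
promoscan run --data-dir data/ --out results/     # full sensitivity grid
```

`promoscan run` evaluates the full grid — promotion thresholds
{2, 5, 10, 15%} × store aggregation {largest, average} × coverage filters
{60, 70, 80, 90%} — and writes per-cell estimates plus a sensitivity
comparison of the two aggregation definitions.

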