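# landfolio

Risk–return efficient land-use portfolios for tropical farms.

`landfolio` answers a land-allocation question that farm economists pose in
Markowitz's portfolio framework: **what fraction of a farm should go to each
land-use option** (here: conventional banana, organic banana, cocoa, maize,
rice, soybean, and balsa/laurel timber plantations in lowland Ecuador) **so
that expected income is maximal for an accepted level of income risk?** It is
aimed at agricultural and forest economists who want the full chain — from
historical price/yield series to efficient frontiers — as tested, scriptable
code rather than a spreadsheet.

## Model

Each option *i* is valued by the annuity of its net revenues *n<sub>t</sub>*
over a *T* = 30-year horizon at discount rate *d* = 0.05 (*q* = 1 + *d*):

```
r_i = [ Σ_t n_t q^(-t) ] · (q − 1) q^T / (q^T − 1)
```

so a perennial crop, a 6-year timber rotation and an annual crop are all
expressed in the same unit, US$ ha⁻¹ yr⁻¹. Uncertainty in *r<sub>i</sub>* is
simulated (1000 repetitions):

* **Joint-year bootstrap** for crops with a 1970–2009 price/yield history
  (shipped as a packaged CSV): every horizon year is drawn with replacement
  from the observed years, keeping that year's price paired with its yield
  and using the same drawn years across crops, so within-year and cross-crop
  dependence survive resampling. Series are first rescaled so their means
  match current price/yield levels (the historical CVs are preserved).
* **Monte-Carlo simulation** for options without a usable history: organic
  banana (conventional banana's price CV ≈ 65% and yield CV ≈ 22% as
  proxies, or a reduced price risk of ±30 US$/Mg on the conventional raw
  price scale) and timber (10% price and growth volatility per rotation).

A land allocation **f** (f<sub>i</sub> ≥ 0, Σ f<sub>i</sub> = 1) then has

```
R_p = Σ_i f_i r_i        σ_p = sqrt( Σ_i Σ_j f_i f_j ρ_ij s_i s_j )
```

and the package solves — *exactly*, by KKT face enumeration rather than an
iterative solver — the minimum-variance portfolio, minimum risk at a return
floor, maximum return under a risk cap σ<sub>p</sub> ≤ c, and whole
efficient frontiers over cap grids.

## Worked example

```python
import landfolio as lf

stats = lf.load_reference_stats()          # published per-option means/SDs
corr  = lf.load_reference_correlations()   # published correlation matrix

mv = lf.min_variance(stats, corr)
print(round(mv.sd, 1), round(mv.expected_return, 1))
# 34.4 192.1
print({c: round(w, 2) for c, w in mv.weights.as_dict().items()})
# {'cocoa': 0.14, 'maize': 0.1, 'soybean': 0.37, 'balsa': 0.15, 'laurel': 0.23}

p = lf.min_risk_at_return(stats, corr, 1040.0)   # income of pure organic banana
print(round(p.sd, 1), {c: round(w, 2) for c, w in p.weights.as_dict().items()})
# 369.5 {'banana': 0.35, 'organic_banana': 0.19, 'rice': 0.47}
```

Reading: spreading the farm over cocoa, maize, soybean and the two timber
species cuts the lowest achievable income SD to ±34 US$ ha⁻¹ yr⁻¹ (the
safest single crop, soybean, has ±52) at an expected 192 US$ ha⁻¹ yr⁻¹; and
the income of pure organic banana (1040 US$ ha⁻¹ yr⁻¹, risk ±843) can be
earned at ±369 by mixing conventional banana, organic banana and rice.

The scenario presets run the same machinery end to end:

```python
res = lf.run_scenario(lf.PRESETS["organic_low_risk"], risk_caps=[500.0])
print(res.point_at_cap(500.0).weights.as_dict())
# {'banana': 0.42..., 'organic_banana': 0.576...}
```

The numbered scripts under `analysis/` (`01_series_statistics.py` …
`04_scenario_comparisons.py`) narrate the full study — series diagnostics,
simulated return distributions, efficient frontiers per scenario, and the
organic-banana gain/correlation sweep — writing their tables under
`results/`. A `landfolio` CLI (`simulate | frontier | scenario | synth`)
exposes the same stages for shell use.

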