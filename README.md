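# pm25elements

Source apportionment, crustal enrichment, meteorological drivers and
inhalation risk for PM2.5-bound elemental concentrations.

Airborne fine particulate matter (PM2.5) carries trace elements whose
mix fingerprints its emission sources — traffic exhaust, biomass
burning, crustal and marine dust, construction — and whose inhalation
drives measurable health risk.  This package implements, as a tested
pipeline, the standard chemometric workflow used to analyse a
three-site Thai monitoring campaign (Chiang-Mai "COS" n=82, Bangkok
"BOS" n=48, Phuket "POS" n=61; 25 elements per 72-h sample): for
atmospheric chemists and exposure scientists who want each stage as a
reusable, seed-deterministic library call rather than a spreadsheet.

The stages, in the order the pipeline runs them:

1. **Site summaries & ratios** — per-site element statistics and
   between-site mean ratios after unit harmonisation to ng/m³.
2. **Enrichment factors** — EF = (C_E/C_Fe)_air ÷ (a_E/a_Fe)_crust with
   Fe reference; log₁₀EF < 1 marks crustal origin, > 4 strong
   anthropogenic enrichment.
3. **Receptor model** — PCA on the correlation matrix, eigenvalue>1
   retention, varimax rotation, absolute principal component scores
   (APCS: regression factor scores shifted by the artificial
   zero-concentration sample) and per-species multiple regression; the
   measured/predicted ratio M/P ≈ 1 validates the fit.
4. **Seasonal diagnostic ratios** — Ca/Al, Na/Mg, Ni/V, ... per season
   bin with one-way ANOVA (three seasons) or pooled t (two) at p<0.05.
5. **Network variable importance** — a small two-hidden-layer sigmoid
   MLP maps nine meteorological covariates (fire hotspots within
   100/200/300 km, albedo, temperature, RH, u/v wind, precipitable
   water) to each element; permutation importance normalised to
   max=100 ranks the drivers.
6. **Inhalation risk** — ADD = C·IR·ED·EFreq/(BW·AT); HQ = ADD/RfD for
   Co/Ni/Cu/Zn/As/Pb; ELCR = LADD·SF (SF = IUR·BW/IR) for Ni/As/Pb,
   for adolescent and adult exposure groups.

Because the campaign's raw per-sample data are not deposited, a
synthetic module generates (a) known-truth source mixtures with
multiplicative noise and injected RH-depletion / hotspot couplings, for
recovery validation, and (b) a calibrated three-site dataset whose
per-site means and standard deviations match the published statistics
exactly.

## Worked example

```python
from pm25elements import table1_fixture, summarise_by_site, site_ratio_table
from pm25elements.enrichment import CrustalReference, enrichment_factor
from pm25elements.risk import risk_from_means

table = table1_fixture(seed=0)            # calibrated three-site dataset
summary = summarise_by_site(table)

ratios, total = site_ratio_table(summary, "BOS", "COS")
print(f"BOS/COS panel total {total:.2f}, Se {ratios['Se']:.2f}")

ef = enrichment_factor(summary, CrustalReference.default(), "Al", "COS")
print(f"log EF(Al) at COS: {ef['logEF']:.2f} ({ef['class']})")

hq = risk_from_means(summary).loc[("HQ", "BOS", "adolescent", "As"), "value"]
print(f"HQ of As at BOS (adolescents): {hq:.3g}")
```

prints

```
BOS/COS panel total 1.47, Se 4.24
log EF(Al) at COS: 1.17 (slightly)
HQ of As at BOS (adolescents): 0.225
```

Bangkok carries ~1.5× the summed elemental burden of the other sites
(4.2× for the traffic tracer Se); aluminium sits just above the crustal
band, i.e. it is dominated by crustal input; and the arsenic hazard
quotient for adolescents at Bangkok is the highest in the campaign but
still below the HQ=1 risk threshold.

The numbered scripts under `analysis/` run each stage end to end and
write their tables to `results/`:

```
python analysis/01_site_summaries.py
python analysis/03_receptor_model.py      # known-truth recovery
python analysis/05_ann_importance.py      # RH ranks first, hotspots second
...
```

A `pm25elements` CLI wraps the same pipeline for file-based use:
`pm25elements demo --seed 1 --out demo/` writes a synthetic input set,
and `pm25elements run --config demo/config.yaml` executes all stages
with provenance-stamped TSV outputs and a JSON manifest.

## Layout

```
src/pm25elements/   library: core, synth, enrichment, receptor,
                    ratios, ann, risk, pipeline, cli, study_tables
analysis/           numbered narrative drivers (write to results/)
scripts/            acceptance script
tests/              pytest suite
docs/methods.md     models, assumptions, defaults, limitations
```
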