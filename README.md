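# vetamu

Quality screening and consumption surveillance of veterinary
antimicrobials for settings without routine sales reporting — the kind
of desk-scale One Health study a veterinary pharmacologist or AMR
surveillance officer runs from retail-outlet field data.

The package covers the full chain from raw field records to normalized
consumption metrics:

1. **Visual inspection** — score sampled medicines against a fixed
   checklist of packaging/labelling criteria (active-ingredient name,
   leaflet, dose statement, expiry date, manufacturer name/address,
   batch number) plus physical criteria; a sample is *compliant* only if
   it passes everything. Summaries give per-criterion failure counts
   (column sums) and noncompliance rates per category and overall.
2. **Retail audit** — estimate units sold per outlet-product from
   repeated stock counts:
   `units = stock_first − stock_last + Σ additions − Σ disposals`,
   a telescoping sum that is exact for any visit schedule when
   corrections are fully logged. Negative estimates are flagged, not
   clipped.
3. **Mass conversion** — declared strengths (mg, g, IU, % w/v, % w/w)
   become grams of active pharmaceutical ingredient (API) per pack;
   IU-labelled products use configured substance-specific IU→mg factors.
4. **Biomass / PCU** — the population correction unit is the total live
   biomass (kg) of the food-producing population at typical treatment
   age: cattle = census × age-class-weighted mean weight; sheep/goats =
   slaughter throughput + (census − n_slaughtered/1.5) × 75 kg retained
   breeding stock; poultry = 1 kg per mature bird excluding young
   chicks.
5. **AMU metrics** —
   `mg/PCU = total API mass (mg) / biomass (kg)` and
   `nDDDvet = total API mass (mg) / DDDvet (mg)`, with category splits,
   route-restricted variants and country-of-origin summaries.

A first-class synthetic-data module simulates outlet stock trajectories
(Poisson demand, threshold restocking, optional under-reported
additions) with known true sales, and constructs inspection fixtures
hitting exact failure-count vectors, so every stage is testable without
field data. A bundled reference survey (44 sampled products, one
audited month, a municipal livestock census from a mid-sized Ethiopian
town) exercises the pipeline against published headline figures.

## Worked example

```bash
python examples/06_full_pipeline.py
```

prints (from the bundled reference survey):

```
samples inspected: 44, noncompliant: 25%
daily antibiotic mass:     4540.7 g
daily anthelmintic mass:   3086.1 g
PCU denominator:         40,615,099 kg
daily mg per PCU:        0.112 mg/kg
```

Half of the antibiotic samples fail at least one checklist criterion
(all anthelmintics pass), about 4.5 kg of antibiotic API move per day —
roughly 60 % of the combined antimicrobial mass, 1.5× the anthelmintic
mass — and normalizing the daily antibiotic mass by the food-producing
biomass gives 0.112 mg of active ingredient per kg. The other examples
(`examples/01…05`) walk through each stage: checklist scoring,
the audit estimator, consumption tables (albendazole 55.8 % of
anthelmintic mass, injectables 62.6 % of antibiotic mass), biomass/PCU,
and estimator recovery on simulations.

The same stages are scriptable from the shell:

```bash
vetamu reference --out-dir in        # or: vetamu simulate --seed 7 --out-dir in
vetamu report --config run.yaml      # full report bundle (JSON + CSV)
```

## Layout

- `src/vetamu/catalog.py` — product model, strength parsing, IU→mg
- `src/vetamu/inspection.py` — checklist scoring and summaries
- `src/vetamu/sales_audit.py` — audit estimator and consumption tables
- `src/vetamu/biomass.py` — species biomass formulas and PCU
- `src/vetamu/amu_metrics.py` — mg/PCU, nDDDvet, splits, origins
- `src/vetamu/synthetic_data.py` — simulator and fixture generators
- `src/vetamu/reference.py` — bundled reference survey dataset
- `src/vetamu/cli.py` — run configuration, pipeline, CLI
- `docs/methods.md` — model assumptions, defaults and limitations
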