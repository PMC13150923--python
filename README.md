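# lexspace

Spatiotemporal analysis of mental-illness-related criminal judgments:
pattern-based case extraction from court text, yearly trend statistics,
emerging space-time hot-spot detection, and geographically & temporally
weighted regression (GTWR) — with a synthetic-data module that emulates every
input and carries exact ground truth.

## The problem

In Taiwan, a citation of **Criminal Code Article 19** in a judgment — the
provision that makes an offence unpunishable or subject to a reduced sentence
when a mental disorder removed or significantly diminished the offender's
capacity — is a usable proxy for a criminal case involving mental illness.
Starting from raw judgment records (JSON objects with `JID`, `JYEAR`,
`JCASE`, `JNO`, `JDATE`, `JTITLE`, `JFULL`), the pipeline:

1. **extracts cases** — screens the unsegmented Chinese text for the three
   exact citation variants (刑法第19條 / 刑法第十九條 / 刑法第１９條), filters
   by court level, collapses appeal chains linked by 不服 {JID} …。 clauses
   into single cases, pulls the FACT section via the 事實 … 。理由 delimiter,
   and geocodes each case by resolving the reporting police office
   (訴由/案經 markers) against a gazetteer, disambiguating colliding short
   names by county mentions in the text;
2. **tests the yearly trend** of the Article-19 proportion with the
   Cochran–Armitage test

   `T = Σᵢ sᵢ(rᵢ − nᵢp̄)`, `Var(T) = p̄(1−p̄)[Σnᵢsᵢ² − (Σnᵢsᵢ)²/N]`, `Z = T/√Var(T)`;

3. **finds emerging hot spots** on a complete district × year space-time cube:
   per-bin Getis–Ord Gi* over queen-contiguity neighborhoods (self included,
   one prior time step pooled), Benjamini–Hochberg FDR across all bins,
   Mann-Kendall trend on each district's Gi* z sequence, and the standard
   emerging-pattern taxonomy (new / consecutive / intensifying / persistent /
   diminishing / sporadic / oscillating / historical, hot or cold);
4. **fits GTWR**: at each district-year, local weighted least squares
   `β̂ᵢ = (XᵀWᵢX)⁻¹XᵀWᵢy` with kernel weights decaying in the space-time
   distance `d = √(Δx² + Δy² + τ²Δt²)` between district centroids, bandwidth
   chosen by leave-one-out cross-validation; outcomes are the mental-illness
   **crime rate** (cases per 10,000 residents) and **case proportion** (per
   100 criminal cases), predictors the per-10,000 densities of mental-health
   resources (beds, psychologists and social workers, psychiatry departments,
   psychiatry doctors) plus socioeconomic covariates. A spatial-lag-of-X OLS
   (`y ~ X + WX`) separates own-district from spillover effects, and
   per-district correlations between the summary resource index
   `beds + 2·(psychologists+social workers) + 3·doctors + 4·departments`
   and mental-illness crime map the bivariate picture.

It is written for epidemiologists and computational social scientists who
want each of these stages as a tested, reusable library function rather than
a GIS-suite black box.

## Worked example

```python
from lexspace import *
from lexspace.judgment_extraction import ExtractionConfig
from lexspace.gtwr import GTWRConfig
from lexspace.synthetic_data import CorpusSpec, PanelSpec, gen_corpus, gen_panel

corpus = gen_corpus(CorpusSpec(n_judgments=1000, seed=1))
cases, report = run_extraction(corpus.judgments, corpus.gazetteer, ExtractionConfig())
print(report.n_input, report.n_article19_raw, report.n_cases_after_dedup,
      report.n_fact_found, report.n_geo_resolved)
# 1000 294 597 588 476
```

Of 1,000 synthetic judgments, 294 cite Article 19; after court filtering the
859 retained judgments collapse into 597 cases (appeal chains merged), 588 of
which have an extractable FACT section and 476 resolve to a district.

```python
panel = gen_panel(PanelSpec(n_districts=100, seed=1))
derived = derive_panel(panel.panel)
events = panel.panel.loc[panel.panel.index.repeat(panel.panel["mh_violent"]),
                         ["district_id", "year"]]
cube, _ = build_cube(events, panel.districts, range(2012, 2022))
trends, bins = emerging_hotspots(cube, alpha=0.05)
print(trends["category"].value_counts().to_dict())
# {'no pattern': 78, 'consecutive hot spot': 17, 'new hot spot': 5}
```

The generator plants a 3×3 block of districts whose violent-crime intensity
grows 1.6× per year from 2016 on; all nine block districts (and their
contiguity ring, which pools the same counts) surface as hot spots while the
far field stays "no pattern".

```python
fit = fit_table_models(derived, panel.districts, outcome="crime_rate",
                       category="larceny", predictors="summary",
                       config=GTWRConfig(bandwidth=4000.0, tau=500.0))
print(fit.summary[["term", "mean", "lo95", "hi95", "stars"]])
#                     term      mean      lo95      hi95 stars
# psychiatry_doctor_per10k  0.323093  0.322468  0.323718   ***
# ...
# n = 1000, ENP = 30.2, R2 = 0.321
```

The panel plants a +0.3 psychiatry-doctor effect on the larceny
mental-illness crime rate; the mean local GTWR coefficient recovers it
(0.323, 95% CI excluding zero).

A command-line interface wraps the same stages:

```bash
lexspace simulate corpus --out data/ --seed 1 --n 1000
lexspace extract --corpus data/judgments.jsonl --gazetteer data/gazetteer.csv \
                 --out cases.csv --report report.json
lexspace run --config pipeline.json   # simulate → extract → trend → hotspots → gtwr → correlate
```

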