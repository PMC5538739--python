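# arscore

**Annual Risk Score (ARS) toolkit for perceiving climate-induced downside
risk during crop production.**

Farm-planning models usually value risk through the variance of monetary
outcomes, which blurs climatic influence with market and policy effects.
The ARS methodology instead scores *mid-season perceptions*: a farmer (or
a modeled farm agent) monitors the crop at scheduled observation points
(OPs) and counts, with binary utility scores, how often the observed state
falls outside an *acceptance range* — the band of fluctuation that
historically was still compatible with an acceptable harvest.  The anchor
of the whole method is the farmer-elicited **still-good yield** (*sgy*):
the lowest yield that still implies profitability.  Yields at or above
*sgy* are acceptable; anything below is downside risk.

`arscore` implements the full chain for winter wheat:

1. **`weathergen`** — a synthetic daily weather generator (sinusoidal
   seasonal mean + AR(1) temperature anomalies, Markov-chain rainfall
   occurrence with gamma amounts, cloud-attenuated clear-sky radiation)
   targeting a temperate climate of 9–10 °C mean annual temperature and
   730–830 mm precipitation.
2. **`cropsim`** — a daily radiation-use-efficiency winter-wheat model
   with BBCH phenology, layered soil water, damped soil temperature,
   BBCH-triggered fertilizations and harvest.
3. **`knowledge`** — the simulated experience pool: a sowing-date ×
   weather-year grid of seasons, filtered by *sgy*, summarised per OP and
   parameter as Tukey boxplot whisker intervals, plus per-sowing-day
   success frequencies for OP 0.
4. **`ars`** — season scoring: per-parameter binary utilities
   α<sub>i,c</sub>, per-OP sums α<sub>t,c</sub> = Σ<sub>i</sub> α<sub>i,c</sub>,
   annual total ARS = α<sub>T,c</sub> = Σ<sub>t</sub> α<sub>t,c</sub>, plus the OP-0
   rule (score 1 when the sowing day's historical success frequency is
   below 0.5).  With the default scheme — 10 parameters × 7 OPs + OP 0 —
   the annual maximum is **71**.
5. **`riskstats`** — mean–standard-deviation comparison of yield and ARS
   series across scenarios, flagging cases where the two rankings diverge.
6. **`survey`** — elicitation triples (peak / still-good / average yield),
   willingness to accept *wta = py − sgy*, and sensitivity typing from
   *sgy* vs *avy<sub>farm</sub>* vs *avy<sub>region</sub>*.
7. **`adaptation`** — year-on-year pool updates (acceptable seasons join
   the distribution, losses below *sgy* teach nothing), expected-ARS
   averaging with pluggable weights, and the per-crop planning constraint.

## Worked example

```python
import arscore

# 31 synthetic weather years -> 30 sowable seasons
climate = arscore.ClimateParams()
weather = arscore.generate_weather(climate, 31, seed=20831)

# the default what-if grid: 46 sowing DOYs (283..328) x 30 years
crop, soil = arscore.CropParams(), arscore.SoilProfile()
grid = arscore.build_grid(weather, range(283, 329), crop, soil)
print(len(grid))                      # 1380

# knowledge pool at the still-good yield of 69.17 dt/ha
pool = arscore.build_pool(grid, sgy=69.17)
print(pool.n_kept)                    # 842 seasons met the threshold
print(pool.op0_freq[283])             # 0.9  (early sowing: 27/30 years ok)
print(pool.op0_freq[328])             # 0.0667 (late sowing rarely acceptable)

# score a fresh season against the pool
trace = arscore.simulate_season(weather, 283, crop, soil, sowing_year=1)
record = arscore.score_season(trace, pool)
print(record.total, "/", record.max_possible)   # 2 / 71
```

The printed numbers mean: the 46 × 30 grid produced exactly 1,380
candidate seasons; 842 of them reached the 69.17 dt/ha threshold and feed
the acceptance ranges; sowing on day 283 succeeded in 90 % of historical
years (OP-0 score 0) while day 328 succeeded in 7 % (OP-0 score 1); and
the scored season deviated from its acceptance ranges in 2 of 71 possible
observations — a calm year.

The same chain is available from the shell:

```bash
arscore run --out results/demo          # full pipeline with defaults
arscore weather --years 31 --seed 1 --out weather.csv
arscore survey --input survey.csv --avy-region 71.4 --out table1.csv
```

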