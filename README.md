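# leafspectra

Tools for analysing leaf-trait variation and the leaf production /
stress-tolerance spectrum of invasive plants surveyed in paired
invaded/uninvaded plots, with exhaustive multimodel inference to
attribute both to biotic and abiotic drivers.

Widespread invaders such as *Solidago canadensis* occupy contrasting
habitats across their invaded range and adjust their leaves in two ways:
individual traits shift (trait variation) and the relationships between
traits shift (the trait spectrum).  `leafspectra` quantifies both for a
survey of populations measured for seven leaf traits — leaf area, SLA,
LDMC, chlorophyll index, leaf C, leaf N and leaf C:N — and decomposes
them over 16 environmental drivers grouped into climate, native plant
diversity, soil properties, and invader–community interactions.

## The quantities it computes

For a trait value $T_i$ of unit $i$, with extremes over the sampled
populations:

- **SLA** = leaf area / dry mass (cm² g⁻¹); **LDMC** = 1000 × dry mass /
  water-saturated fresh mass (mg g⁻¹).
- **Δ (relative change)** = $(V_i - V_u)/(V_i + V_u)$ for a variable
  measured in the invaded ($V_i$) and paired uninvaded ($V_u$) plot —
  the invader–community interaction metric, bounded in [−1, 1].
- **PVI (phenotypic variation index)**
  $= \dfrac{\max(T) - T_i}{\max(T) - \min(T)}$ — 0 at the sample
  maximum, 1 at the minimum.
- **LPI / LTI (leaf production / stress-tolerance index)**
  $= \sum_j T_{ij}/\max_i(T_{ij})$ over the four production traits
  (leaf area, SLA, chlorophyll, leaf N; range (0, 4]) and the three
  tolerance traits (LDMC, leaf C, leaf C:N; range (0, 3]); the per-unit
  ratio LTI/LPI locates a unit on the spectrum.
- **SMA (model-II) fits** for trait–trait and LPI–LTI relationships:
  slope $= \operatorname{sign}(r)\, s_y/s_x$, significance from the
  correlation test.
- **Multimodel inference**: all $2^{16}$ candidate OLS models over the
  standardized drivers are ranked by
  $\mathrm{AICc} = n\ln(\mathrm{RSS}/n) + 2k + 2k(k+1)/(n-k-1)$;
  Akaike weights $w_m \propto e^{-\Delta_m/2}$ give model probabilities;
  a driver's **importance** is the summed weight of models containing
  it, its **relative contribution** is importance as a share of total
  importance, and effect directions come from model-averaged
  coefficients over the 95% cumulative-weight confidence set.  Category
  totals and per-capita (per-driver) contributions plus a biotic/abiotic
  split summarise the decomposition.

Because the environmental tables of real surveys are rarely deposited,
the package ships a first-class synthetic survey generator
(`leafspectra.synthetic`) reproducing the field geometry — 22 locations
× 3 sites, 51 five-pair and 15 three-pair sites, hence 300 plot pairs
in 66 populations — with a known linear effect structure, so the whole
chain can be validated against ground truth.

## Worked example

```python
from leafspectra import build_index_table, pvi_anova, simulate_survey, sma_fit
from leafspectra.indices import TRAIT_COLUMNS

bundle = simulate_survey(seed=42)
table = build_index_table(bundle.trait_table)
fit = sma_fit(table["lpi"], table["lti"])
print(f"LPI-LTI SMA fit: slope={fit.slope:.3f}, r^2={fit.r_squared:.3f}, n={fit.n}")
```

prints

```
LPI-LTI SMA fit: slope=-0.598, r^2=0.285, n=300
```

— a negative model-II slope, i.e. a production–tolerance trade-off in
this simulated survey, with 28.5% of the variation in one index
explained by the other.  Feeding the spectrum ratio to the multimodel
engine (`examples/driver_contributions.py`):

```
candidate models: 65536
95% confidence set: 896 models

per-category totals and per-capita (per-driver) contributions:
              total_pct  n_members  per_capita_pct
climate           20.85          2           10.43
diversity         20.82          2           10.41
soil              26.71          6            4.45
interactions      31.61          6            5.27
```

The drivers given true effects in the generator (`map`, `evenness`,
`nutrients`, `d_nutrients`, …) each capture ≈ 10% of total importance
with significance stars, while pure-noise drivers sit near the 2–3%
baseline; per-capita values make the 2-driver and 6-driver categories
comparable.

The `examples/` directory holds one short script per capability
(simulation, indices, spectrum regression, driver contributions, full
pipeline), and the `leafspectra` command exposes the same stages as
shell subcommands (`simulate`, `indices`, `spectrum`, `mmi`, `report`).

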