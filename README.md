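# nbssbench

Benthic **normalized biomass size spectra** (NBSS) from per-organism
measurements, with the supporting multivariate community statistics.

Soft-bottom communities — meiofauna sieved between 32 and 500 µm,
macrofauna retained on 500 µm — partition their biomass across body
sizes in a strikingly regular way. Binning individual dry masses *m*
(µg) into log₂ size classes (class *n* holds 2ⁿ ≤ *m* < 2ⁿ⁺¹; class 4
spans 16–32 µg), dividing each class's total biomass by its width
Δ = 2ⁿ, and regressing log₂ of that *normalized biomass* (NB) on the
class index gives a nearly straight line

&nbsp;&nbsp;&nbsp;&nbsp;log₂ NBₙ = *a* + *b·n*

whose slope *b* (≈ −1 in energetic steady state, −0.5…−1.3 in benthic
systems) and intercept *a* summarise community size structure and
standing stock. This package implements the full chain needed to
estimate and compare those parameters across sites, for ecologists
working with fjord or shelf infauna samples:

* **allometry** — length/width (mm) → biovolume via the Feller–Warwick
  shape formula *V = L·W²·c* (cylinder for nematodes) → wet mass at a
  specific gravity of 1.13 (1 mm³ ≙ 1.13 mg) → dry mass (0.25·WM for
  meiofauna; taxon DM/WM factors for macrofauna), with fragment-length
  calibration, subsample expansion and standardisation to 0.1 m².
* **spectra** — bit-exact log₂ binning, per-station and pooled spectra,
  component combination (meiofauna + macrofaunal nematodes + macrofauna),
  normalization.
* **nbss** — OLS spectrum fits with Cook's-distance diagnostics, ANCOVA
  slope-homogeneity tests across sites, common-slope ("fixed slope")
  intercept estimates with Tukey-adjusted pairwise comparisons, and
  Spearman correlations of intercepts with standing stock over full or
  truncated class ranges.
* **community_stats** — Euclidean/Bray–Curtis resemblance matrices,
  seeded one-way PERMANOVA (exhaustive enumeration for small designs),
  RELATE/Mantel rank correlation, DistLM with marginal tests and
  forward selection on adjusted R², and gamma/log-link GLMs of body
  mass on temperature.
* **synthetic_data** — a generator producing organism tables whose
  binned, normalized biomass follows a configurable NBSS line with
  realistic bimodal structure, so every stage can be tested against
  known truth.

## Worked example

Generate a six-fjord community (three stations each, true slope −0.53,
true intercept 11 with environment-linked station variation), run the
pipeline and compare fjords:

```python
from nbssbench import ScenarioConfig, generate_community, pipeline, nbss

samples, profiles, truth = generate_community(ScenarioConfig(seed=42))
converted = pipeline.convert_samples(samples)           # allometry chain
comp = nbss.compare_slopes(pipeline.grouped_normalized(converted))
print(f"interaction F({comp.df_num}, {comp.df_den}) = {comp.interaction_F:.2f}, "
      f"p = {comp.p_interaction:.2f}")
print(f"common slope = {comp.common_slope:.3f} +/- {comp.common_slope_se:.3f} SE")
```

prints

```
interaction F(5, 502) = 0.04, p = 1.00
common slope = -0.524 +/- 0.014 SE
```

— the class-by-fjord interaction is far from significant (slopes are
homogeneous, as constructed), and the pooled slope recovers the
generating value within one standard error. The common-slope intercepts
(`comp.intercepts`) range here from 8.98 ± 0.29 (F6) to 12.63 ± 0.28
(F3), tracking each fjord's food-availability covariates;
`nbss.pairwise_intercepts(comp)` gives the Tukey-adjusted contrasts.
`pipeline.totals_table(converted)` reports station standing stocks
(6.7–110 g DM m⁻² per fjord in this draw) and a macrofaunal share of
total dry mass of 0.986.

The same steps are available from the shell:

```bash
nbss-bench simulate --seed 42 --out sim/
nbss-bench compare sim/organisms.csv --stations sim/stations.csv
nbss-bench permanova sim/organisms.csv --stations sim/stations.csv --seed 1
```

## File formats

`organisms.csv` (comma- or tab-delimited by extension): `fjord_id,
station_id, gear, taxon_id, group, species, genus, family, length_mm,
width_mm, count_weight, is_fragment, feeding_type, dry_mass_ug` —
`group` is one of `meiofauna | macrofauna | macrofaunal_nematode`;
`count_weight ≥ 1` carries subsample expansion. `stations.csv`:
`fjord_id, station_id, gear, sampled_area_cm2` (1000 for a van Veen
grab, 10 for a syringe core). `environment.csv`: `fjord_id, station_id,
temperature_C, salinity, c_org_pct, delta13C, chl_a_ug_g, cpe_ug_g,
mud_pct`. Conversion constants (Feller–Warwick coefficients, DM/WM
factors, direct length→mass regressions) are a JSON/YAML document
mirroring `ConversionConfig`; the shipped defaults are documented
example values and should be replaced with study-specific tables for
real analyses.

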