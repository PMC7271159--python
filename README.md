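# gppattrib

Attribution of centennial-scale changes in **gross primary productivity
(GPP)** — the gross photosynthetic CO₂ uptake of land ecosystems, the
largest carbon flux on land — to the factors that drive them: climate,
land use and land cover change (LULCC), CO₂ fertilization, nitrogen
deposition, and natural versus anthropogenic forcing.

The package is written for carbon-cycle and Earth-system-model analysts.
It implements the *dual-constraint* attribution workflow used with
semi-factorial ensembles of offline land-surface models (runs RG1 → SG1 →
SG2 → SG3 → BG1, each enabling one more time-varying factor) and coupled
Earth-system models (piControl / historicalNat / historicalGHG /
historical):

* **Simulation differencing** — two runs that differ by exactly one
  enabled factor are subtracted; the difference is the effect of that
  factor (SG3 − SG2 → CO₂; historicalNat − piControl → natural forcing).
  Effects telescope exactly: climate + LULCC + CO₂ + N = BG1 − RG1.
* **One-model-one-vote consensus** with bootstrap ensemble-spread
  uncertainty (1000 replicates, 90% intervals) for decadal global series,
  per-cell change maps and dominance maps.
* **Random-forest climate emulation** — per-grid-cell forests trained on
  the climate-only run (monthly GPP vs tas/pr/rsds) decompose the net
  climate effect into temperature, precipitation and radiation
  contributions by sequential driver substitution (first-order only;
  skill reported as out-of-bag R²).
* **Change diagnostics** — Δ mean annual GPP and Δ seasonal amplitude
  (1981–2010 minus 1901–1930), deseasonalized interannual-variability
  ratio, bootstrap significance masks, area-weighted global integrals in
  Pg C a⁻¹.
* **Derived analyses** — critical-load screening of the nitrogen effect
  (10 and 3 kg N ha⁻¹ a⁻¹ thresholds), the CO₂ vegetation-feedback
  correction (÷1.3), and decadal driver–GPP correlations.
* A **synthetic factorial-ensemble generator** that emulates both
  archives at desk scale with known per-factor ground truth, so every
  estimator in the package is verifiable against exact answers.

Real archives (CF-style netCDF, kg C m⁻² s⁻¹ or g C m⁻² month⁻¹) are read
with `read_flux`/`read_drivers`, conservatively regridded and masked; the
synthetic generator writes the identical layout.

## Worked example

```python
import gppattrib as ga

# an 11-model factorial world, 1901-2010, with known truth
archive = ga.generate_factorial_ensemble(ga.TruthConfig(seed=1))
w, mask = archive.weights, archive.mask

for factor in ("climate", "LULCC", "CO2", "Ndep"):
    effects = ga.archive_effects(archive, factor)          # differencing
    df = ga.decadal_series(effects, w, mask, seed=1)       # consensus + CI
    last = df.iloc[-1]
    print(f"{factor:8s} 2001-decade effect {last['mean']:+6.2f} "
          f"[{last['ci_low']:+6.2f}, {last['ci_high']:+6.2f}] Pg C/a "
          f"(n={last['n_models']})")
```

prints

```
climate  2001-decade effect  +1.73 [ +1.62,  +1.84] Pg C/a (n=11)
LULCC    2001-decade effect  -0.96 [ -1.06,  -0.86] Pg C/a (n=11)
CO2      2001-decade effect +19.98 [+18.02, +22.16] Pg C/a (n=11)
Ndep     2001-decade effect  +9.20 [ +8.12, +10.28] Pg C/a (n=4)
```

i.e. in this synthetic world CO₂ fertilization dominates the final
decade's GPP enhancement, nitrogen deposition is second (estimated from
the four nitrogen-capable models only), climate change is a small
positive "climate fertilization", and land conversion is a small loss —
each with its 90% ensemble-spread interval.  The generator's stored truth
fields confirm the estimates to within ~1%.

A command-line interface mirrors the library:

```bash
gppattrib synth     --seed 1 --out archive_dir      # write netCDF ensemble
gppattrib changes   --seed 1 --out out_dir          # Fig-style change maps
gppattrib attribute --seed 1 --out out_dir          # decadal factor table
gppattrib decompose --seed 1                        # RF climate decomposition
gppattrib all       --seed 1 --out out_dir          # full pipeline
```

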