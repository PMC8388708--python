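# beltcover

Hourly manure-coverage quantification on the manure belt of caged layer
houses, for ammonia-emission modelling.

In a manure-belt layer house, the hourly ammonia emission is
`M_NH3 = ER × A_s`, where `ER` (mg·m⁻²·h⁻¹) is the emission rate per unit
manure surface produced by an upstream mechanistic model, and `A_s` is the
emitting manure surface area. `A_s` is well approximated by the projected
manure area on the belt, which grows as hens deposit droppings and resets
when the belt is cleared. `beltcover` provides the full measurement and
prediction chain for that area:

* **Image measurement** — plan-view photographs of a white 0.86 m × 0.68 m
  collection plate are converted to grayscale, thresholded at a global
  intensity T = 200, and the manure coverage proportion (MCP) is the black
  pixel fraction: `γ = n_black / n_total × 100 %`. The projected area is
  `A_p = γ/100 × A_plate`.
* **Growth-curve models** — quartic polynomials
  `MCP(h) = c₄h⁴ + c₃h³ + c₂h² + c₁h + c₀` in hours `h` since the last belt
  clearing, with packaged published coefficients for 48-h (`mcp48`) and 24-h
  (`mcp24`) clearing schedules, plus the literature daily baseline
  `MCP = min(d/3, 1)`. An OLS `MCPCurveModel`/`MCPCurveResults` pair
  (statsmodels-style) re-fits the quartic to any hourly series.
* **Deposition simulator** — a marked germ-grain (boolean) process: Poisson
  dropping arrivals at day/night mass rates, lognormal dropping masses,
  elliptical footprints with `area = k·m^(2/3)`, and exact union-coverage
  ground truth on a fine occupancy grid. The analytic oracle is the boolean
  closed form `C = 1 − exp(−S/A)`. Rendered images carry realistic dark
  interiors and bright urate speckles, so the measurement chain can be
  validated end to end without field photographs.
* **Production statistics** — photoperiod-driven four-stage segmentation of
  a 48-h experiment (day1/night1/day2/night2), stage-wise increment
  statistics, weekly feed-to-manure ratios, Pearson correlation with t-test,
  and stocking density. Weekly production tables for hen ages 10–30 weeks
  ship with the package.
* **Emission scaling** — `A_T = CP_i/100 × A_plate × N_cage` scales plate
  coverage to the whole house, and an hourly `M_NH3` series couples any MCP
  model to an ER input series.

## Worked example

```python
>>> from beltcover import load_default_models, eval_mcp, HouseSpec, hourly_emission_series
>>> models = load_default_models()
>>> eval_mcp(models["mcp48"], 48)   # coverage % two days after clearing
82.22773856
>>> eval_mcp(models["mcp24"], 24)   # coverage % one day after clearing
59.46031839999999
```

One day after belt clearing about 60 % of the belt is covered; after two
days about 82 % — the overlap of fresh droppings onto existing manure damps
the second day's growth even though the hens drop just as much mass.

Re-fitting the quartic to the packaged synthetic 21-week mean curve (126
simulated plate series, six plates per hen age):

```python
>>> from beltcover.fixtures import load_weekly_mean_fixture
>>> from beltcover import MCPCurveModel
>>> fx = load_weekly_mean_fixture()
>>> print(MCPCurveModel(fx["mcp_mean_pct"], fx["hour"]).fit().summary())
Quartic MCP growth-curve fit (OLS)
==============================================
observations                48
hour domain             1 - 48
R-squared               0.9989
----------------------------------------------
term                coef       std err
h^4         -4.36981e-05      4.37e-06
h^3           0.00492015      0.000431
h^2            -0.212997        0.0141
h^1              5.47465         0.173
h^0             -2.17436         0.625
==============================================
```

Scaling to a 438-cage house at a constant ER of 50 mg·m⁻²·h⁻¹:

```python
>>> out = hourly_emission_series(models["mcp48"], HouseSpec(n_cage=438), er=50.0, hours=[1, 12, 24, 48])
>>> print(out.to_string(index=False))
 hour    cp_pct     a_t_m2   m_nh3_mg_h  in_domain
    1  0.814787   2.087016   104.350801       True
   12 38.696366  99.117800  4955.889999       True
   24 61.826548 158.364004  7918.200215       True
   48 82.227739 210.620103 10531.005151       True
```

At hour 24 roughly 158 m² of belt is emitting, releasing ~7.9 g NH₃ per
hour house-wide at this ER.

The same pipeline is available from the shell:

```sh
beltcover simulate --config run.yaml      # images + ground-truth CSV + manifest
beltcover measure  run_dir/               # coverage series CSV from images
beltcover fit      run_dir/coverage_series.csv
beltcover emission --model mcp48 --er-const 50 --n-cage 438 --out emission.csv
```

## Layout

- `src/beltcover/imaging.py` — photograph → binary image → coverage
- `src/beltcover/simulate.py` — germ-grain deposition simulator + renderer
- `src/beltcover/models.py` — quartic MCP models, OLS fit, boolean oracle
- `src/beltcover/production.py` — stages, ratios, correlation statistics
- `src/beltcover/emission.py` — house-level area and NH₃ scaling
- `src/beltcover/fixtures.py` — synthetic 21-week mean curve generator
- `src/beltcover/cli.py` — `beltcover` command-line entry points
- `docs/methods.md` — model assumptions, calibration and limitations
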