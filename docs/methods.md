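# Methods

## Coverage measurement

A plate photograph is reduced to a coverage proportion in three steps:
BT.601 luminance grayscale (weights 0.299/0.587/0.114, rounded to nearest
integer), global threshold at T = 200 (a pixel strictly below T is manure,
a pixel at or above T is plate background — equality is background because
only values *smaller* than the threshold are object), and exact pixel
counting. Coverage γ is a pure pixel ratio, so it is independent of image
resolution and needs no pixel-to-metre calibration; the physical area
follows from the known plate geometry (0.86 m × 0.68 m = 0.5848 m²).
Photographs are assumed cropped to the plate extent by the fixed-camera
protocol; no perspective correction is applied. Hours are 1-based and
sampled at the end of the hour, counting from the most recent belt
clearing.

The choice of grayscale weights is not critical: only pixels within ±1
intensity of T can flip, and manure interiors (≈80) and plate background
(255) sit far from the threshold.

## Deposition model

Hourly deposition on one plate is a marked germ-grain (boolean) process:

* **Arrivals** — the number of droppings per hour is Poisson with mean
  `rate × hens_per_plate / mean_dropping_mass`, so the expected deposited
  mass per hour equals `rate × hens_per_plate` grams. Day and night rates
  differ (packaged weekly values range 7.0–11.9 g·hen⁻¹·h⁻¹ by day,
  3.7–6.2 at night; 8 hens per plate).
* **Marks** — dropping masses are i.i.d. lognormal with mean 5 g and sd
  2 g, giving ~12 droppings per plate-hour at week-12 daytime rates.
  Footprints are ellipses with axis ratio uniform in [0.6, 1.0], orientation
  uniform, and area `a = k · m^(2/3)` (geometric scaling of a deposited
  blob).
* **Placement** — centres are uniform on the plate. Default boundary mode
  `clip` truncates grains at the plate edge (the physical situation);
  `torus` wraps periodically and exists solely to validate the simulator
  against the closed form `C = 1 − exp(−S/A)` without edge effects, where
  `S` is the cumulative pre-overlap footprint area.

Ground-truth union coverage is maintained on a 2000 × 1600 occupancy grid
(0.43 mm pixels; discretisation error < 0.1 % for grains ≳ 2 cm). Mass is
conserved exactly and coverage is non-decreasing by construction.

**Calibration.** The area coefficient `k` is set by inverting the boolean
law: the mean footprint `ā = −A·ln(1 − 0.60)/N` makes the expected
first-day dropping count `N` reach 60 % coverage at hour 24, the regime
field measurements report; dividing by `E[m^(2/3)]` of the mass law gives
the default `k = 8.2 cm²·g^(−2/3)` at week-12 rates (`ā ≈ 23.6 cm²`, a
~5.5 cm blob from a 5 g dropping). Under these defaults a 48-h run shows
the four-stage pattern: mean hourly coverage increments ≈ 3.6 %/h (day 1),
1.2 %/h (night 1), 1.5 %/h (day 2, damped by overlap despite the equal
daytime mass rate) and 0.5 %/h (night 2), with hour-24 coverage
58.9 ± 2.9 % over replicates.

**Rendering.** Images are drawn at a configurable resolution (default
1000 px on the long side): background 255, dropping interiors 80 with
Gaussian noise of sd 5 clipped to [60, 100] (always below threshold), and
urate speckles at intensity 230 on a random 3 % of manure pixels. The
speckle fraction is the measurement-bias dial: thresholding loses exactly
the speckled pixels, so measured γ underestimates truth by `u·γ`; u = 0.03
keeps the bias inside the ±3.3 % maximum relative discrepancy reported for
field photographs. Without urate the render→measure round trip agrees with
grid ground truth to well under 0.5 % absolute.

## Growth-curve models

`QuarticModel` evaluates `c₄h⁴ + … + c₀` with clamping to [0, 100] % on by
default (the published 48-h curve has constant term −4.105 and is negative
near h = 0) and a warning when evaluated outside its fitted domain.
The published coefficients give MCP48(48) = 82.23 % and
MCP24(24) = 59.46 %. Note the published 48-h quartic attains its maximum
(83.04 %) at h = 45 and declines ~0.8 points by h = 48; downstream
monotonicity holds only up to the peak. Evaluated at h = 24, the 48-h curve
gives 61.8 % while the 24-h curve gives 59.5 %; both are reported and no
reconciliation is forced.

`MCPCurveModel.fit()` is ordinary least squares on the quartic basis
(numpy.polyfit), uniform weights, fitting the across-plate mean MCP per
hour; R² = 1 − SS_res/SS_tot about the mean, unadjusted. The fit is an
exact projection: refitting its own fitted values reproduces the
coefficients to 1e-10.

The daily baseline `min(d/3, 1)` and the boolean closed form
`1 − exp(−S/A)` are provided for comparison; the latter is the simulator's
independent analytic oracle and reproduces the overlap damping: with
constant hourly fresh-area input its increments decrease hour over hour.

## Synthetic 21-week fixture

`data/synthetic_weekly_mean_mcp.csv` is a synthetic stand-in for a 21-week
campaign mean curve: six plates per hen age (weeks 10–30), each simulated
48 h at that week's packaged rates and photoperiod, with the footprint
coefficient re-calibrated per age to the 60 %-at-24-h regime. The per-age
calibration encodes the observed age-invariance of the coverage curve: the
field finding is that hourly coverage increments do not track the growing
manure mass (weight–coverage increment correlation ≈ 0.1), and a single
mass-proportional footprint coefficient would contradict it by saturating
the plate faster for older hens. The SD column is the dispersion across all
126 plate series per hour, the error-bar convention of campaign plots.

The quartic fit to this fixture yields R² = 0.999 and stays inside the
per-hour SD band at hours 2–48. At hour 1 the quartic's systematic
near-origin undershoot (~1.3 points, the same artefact that makes it
negative at h = 0) slightly exceeds the synthetic band, which is tighter
than field dispersion because the generator has no plate-handling or
behavioural noise; the band test therefore starts at hour 2.

## Production statistics

Stages partition a 48-h test with lights on at hour 1: day1 = [1, L],
night1 = [L+1, 24], day2 = [25, 24+L], night2 = [24+L+1, 48], L the
photoperiod (13–17 h by age). Stage statistics use the sample (n−1)
standard deviation. The weekly "feed-to-manure ratio" follows the field
convention of daily manure mass divided by daily feed mass
(`(day_rate·L + night_rate·(24−L)) / feed`), which reproduces the packaged
weekly table within printed rounding (±0.03) for 19 of 21 weeks; the
weeks-23 and 25 rows of the source table are internally inconsistent with
their own rates and photoperiod (reconstruction differs by 0.06–0.08).
Pearson correlation uses the standard t-transform for its two-sided
p-value.

## Emission scaling

`A_T = CP_i/100 × A_plate × N_cage`; `M_NH3 = ER × A_s` with `A_s ≈ A_p`
(manure buried under overlaps contributes little to release; the
approximation is recorded in the output's metadata). ER is always an input
series — the upstream mechanistic emission model is out of scope. `N_cage`
is mandatory configuration with no default. Hours outside the MCP model's
domain are computed but flagged.

## Problem sizes and determinism

Monte-Carlo validations use 12–50 replicates of 12–48 h runs and
125–200 plate-hours for rate recovery (1000–1600 hen-hours); at these sizes
every stochastic check passes at 3 standard errors. Each experiment
consumes a single NumPy RNG stream seeded from its parameters, and every
output directory carries a manifest with the seed, so runs are
bit-reproducible.

## Limitations

The generator omits hen behaviour (perch and feeder position preferences,
post-feeding defecation bursts), manure drying and spreading, pile height,
and plate-handling disturbance; centres are uniform and hourly arrivals are
homogeneous Poisson. Passing tests therefore demonstrate correctness of the
measurement and modelling chain against the boolean-process ground truth,
not fidelity of any specific farm's spatial deposition pattern. pH and
moisture-content columns in the weekly table are carried as metadata only
and never modelled.
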