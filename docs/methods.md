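# Methods

## Model and conventions

The concentration is modelled in transfer-function form

    A(q) y(t) = mu + SUM_i B_i(q) u_i(t) + C(q) e(t)

with A(q) = 1 + a1 q^-1 + ... + a_na q^-na and C(q) likewise monic;
B_i(q) = b_{i,1} q^-nk + ... + b_{i,nb_i} q^-(nk + nb_i - 1).  Sign
convention: the stored `a` are the coefficients of A, so a stable, highly
persistent process has a1 close to -1.  The dead time `nk` defaults to 1
(the weather acts from the previous hour); it is shared by all inputs.

The explicit intercept `mu` is this package's deliberate extension of the
classical form.  Indoor radon has a large weather-independent source term
(soil-gas entry, building materials); without a constant the model could
only represent it through the near-constant pressure channel, which makes
the noise-free identification problem ill-posed and entangles the baseline
with the pressure gain.  `mu` is estimated jointly with the other
coefficients (one extra regression column).  A side effect worth knowing:
an input channel that is constant over the creation window is now exactly
collinear with the intercept and is reported as a degeneracy naming the
channel.

## Estimation

`estimate_pem` minimises the sum of squared one-step prediction errors:

1. **Stage 1** — a long ARX fit (lag ~10, shrunk if data are scarce) gives
   preliminary residuals.
2. **Stage 2** — linear least squares on the full regression vector
   (lagged outputs, lagged inputs, lagged stage-1 residuals, constant).
3. **Refinement** — damped Gauss–Newton on the exact prediction-error
   loss: residuals are obtained by filtering A·y − ΣB·u − mu through
   1/C(q) per contiguous valid run (zero initial state), the Jacobian by
   filtering the regression columns through 1/C(q).  Step halving down to
   2^-16; stop when the relative loss change falls below 1e-9 or after 200
   iterations.  C(q) is projected to the invertible region (roots on or
   outside the unit circle reflected inside) after every step.

Stability of A(q) is *not* enforced: an explosive fit is reported (and
free-run simulation warns) rather than rejected, because short creation
windows with strong trends legitimately produce near-unit-root estimates.

Masked samples partition the record into contiguous valid runs.  No
regression vector spans a hole, the residual recursion restarts at zero in
each run, and the first max-lag samples of every run are excluded from the
loss.  A fit requires at least 10x (parameter count) usable rows
(configurable).

Degenerate regressions (smallest singular value below 1e-10 of the
largest) raise an error that names a constant input channel when one is
the cause.

## Simulation

Free-run simulation is a linear filter: v = mu + ΣB·u (+ C·e when
innovations are supplied), then y = v / A with initial conditions taken
from the seed values.  Validation simulations start at the split `h`
seeded with the last `na` *measured* values before `h` (nearest valid
sample substituted under a mask), so the simulated curve starts from
reality.  Input lags before the start of a from-zero simulation are zero
by convention; simulations meant to start in statistical equilibrium
(the generator, long-horizon extrapolation, bootstrap replicas) instead
hold the first input value backwards in time, which suppresses a start-up
transient of order mu/A(1).

## Order selection

The grid search evaluates every combination of (na, nb_P, nb_T, nb_U,
nb_W, nc) up to per-index maxima (default 3, i.e. 4^6 cells; the criterion
runs use 2).  Scores are computed on the validation window from a free-run
simulation; both the squared-area criterion (`sse`, default) and the
absolute mean mismatch (`mean_match`) are recorded for every cell.  Failed
cells score +inf with the cause logged.  Exact score ties go to the
smaller total parameter count, then the lexicographically smallest index,
making the selection independent of iteration order.

A practical caveat the tests quantify: free-run validation SSE separates
*under*-parametrised cells sharply but *over*-parametrised neighbours only
weakly (their extra coefficients are near zero, and with a 0.995-AR(1)
pressure channel an extra pressure lag is ~99.5 % collinear with the
first).  Exact six-index recovery is therefore rare even when the selected
cell's validation SSE is within a few percent of the true cell's; treat
the selected cell as "a parsimonious member of the equivalence class that
validates best", not as a consistent structure estimate.

## Flattening

First differences are taken inside contiguous valid runs of each screened
channel; a sample is flagged when its modified z-score
|d − median| / (1.4826 · MAD) exceeds the threshold (default 3.5, the
classical outlier cutoff).  If MAD is zero, samples with nonzero deviation
are flagged (infinite z) and an all-equal-difference channel flags
nothing.  Flagged samples ± a guard (default 2) are invalidated across
*all* channels: a removed interval removes the whole time slice, keeping
time alignment while honouring the idea of deleting the interval.
Flattening is monotone (it only shrinks the valid set).  Note that the
generator's wind channel is exponentiated-AR(1) and hence genuinely
heavy-tailed: screening wind at low thresholds removes real gusts, which
is defensible but is why the false-positive tests screen temperature and
humidity (also the channels where abrupt artefacts are planted).

## Long-period (annual) mean

`extrapolate_period_mean` free-runs the fitted model over user-supplied
historical weather (e.g. 8760 h).  The recursion is seeded at the model's
steady state for the first weather sample.  The 95 % interval is a
residual-bootstrap percentile interval: innovations are resampled i.i.d.
from the fit residuals; when the creation data are passed, each replicate
also re-estimates the parameters on a parametric replica of the creation
window, so the interval carries estimation uncertainty as well as
innovation uncertainty.  Coverage tests against the generator show this
interval is honest in width but still mildly anticonservative (~85–90 %
empirical coverage of the realized annual mean) when the creation window
covers a single season: a same-season window induces a small systematic
misattribution between the intercept and the seasonal channels that
resampling conditional on that window cannot re-centre.  Longer or
season-spanning campaigns reduce it.

## Synthetic scenarios

The generator encodes the phenomenology the method assumes, with every
constant exposed in `ScenarioConfig`:

| channel | model | defaults |
|---|---|---|
| pressure | AR(1) around 1013 hPa | phi 0.995, innovation sd 0.3 hPa |
| temperature | annual + diurnal sinusoid + AR(1) | mean 12 °C, amplitudes 8 / 4 °C, phi 0.9, sd 0.6 |
| humidity | anti-correlated with T, clipped [20, 100] % | mean 65 %, −1.5 %/°C, AR(1) sd 2 |
| wind | exp(AR(1)), always ≥ 0 | log-mean 0.7, phi 0.9, log-sd 0.2 |

Radon is simulated from a *known* first-order ARMAX on the clean weather:
gains (−0.3, −0.25, +0.10, −1.0) per (hPa, °C, %, m/s) — concentration
rises with humidity, falls with temperature and wind, responds negatively
to pressure — a1 = −0.9 (time constant ≈ 10 h), c1 = 0.3, innovation sd
6 Bq/m³, and an intercept solved so the long-run mean is 130 Bq/m³.  The
resulting series has a winter/summer ratio ≈ 1.7 and a clear 24-h
spectral line.  Negative samples are rectified to zero with the fraction
logged (zero under the defaults; a scenario error above 20 %).

Planted transients are square pulses (default 3 samples) added to the
*recorded* temperature/humidity only — the radon keeps following the clean
weather, emulating sensor-local disturbances — with amplitudes of ≥ 8
robust SDs of the channel's differences and signs chosen to keep humidity
physical.  Positions, durations and amplitudes are stored as ground truth.

What the generator deliberately does **not** emulate: inverse-seasonality
dwellings, occupancy/ventilation regime switches, nonlinear soil-gas
physics, instrument dead time and counting statistics.  Passing tests
therefore demonstrate correctness of the identification machinery under
the model's own assumptions, not forecasting skill on arbitrary real
buildings; on a correctly specified scenario the validation bias is 1–2 %
at *every* creation length, so real-data bias levels of tens of percent
should be read as misspecification, not estimator noise.

## Problem sizes used by tests and the acceptance script

Seeded panels use campaign-scale records: 1400-h scenarios for the
bias-vs-window panels, 1500 h for the 3^6-grid order-recovery study
(50 replicates in the suite, 15 in the acceptance script), 1000-h
contaminated scenarios (8 pulses, 12 robust SDs, 4 samples) for the
flattening comparison, and 8760-h years for coverage and spectrum checks
(20 replicates in the suite, 10 with 100 bootstrap replicates each in the
acceptance script).  These sizes match the intended use (weeks-to-months
of hourly data) and keep every stage's estimation problem comfortably
over-determined.

## Known limitations

* Single-output: one radon series; multi-room records need one model each.
* The create/validate split is a single cut, not cross-validation.
* The bootstrap interval is conditional on the observed weather and
  creation window (see above).
* Timestamps are naive (fixed-offset); daylight-saving arithmetic is out
  of scope.
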