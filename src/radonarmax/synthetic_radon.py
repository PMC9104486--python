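"""Synthetic coupled weather + indoor-radon scenarios with known ground truth.

The generator emulates the statistical structure the forecasting method
assumes: hourly sampling; weather channels with realistic persistence
(pressure a slow AR(1) random walk around 1013 hPa, temperature an annual
plus diurnal sinusoid with AR(1) noise, humidity anti-correlated with
temperature and clipped to a physical range, wind an exponentiated AR(1));
and a radon series produced by simulating a *known* ARMAX model on the clean
weather plus coloured innovations.  The sign pattern of the true input gains
encodes the usual indoor-radon phenomenology: concentration rises with
humidity, falls with temperature and wind, and responds (negatively, via
soil-gas advection) to pressure changes.  A positive constant load term
keeps the series well away from zero; residual negative samples are
rectified to zero and the rectified fraction is reported.

Optionally the generator plants abrupt square-pulse transients into the
*recorded* weather channels (the radon series keeps following the clean
weather) — the disturbance the flattening pre-treatment is designed to
remove.  All ground truth (true parameters, transient positions, realized
long-period mean) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .armax_core import ARMAXOrder, ARMAXParameters, simulate_free_run
from .errors import ParameterError, ScenarioError
from .preprocessing import MAD_SCALE
from .series_io import CHANNELS, SeriesBundle

HOURS_PER_YEAR = 8760


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic campaign.

    Defaults describe a temperate-climate dwelling monitored from early
    March (matching a typical continuous-monitor campaign) with a mean
    indoor concentration of 130 Bq/m3 and hourly sampling.
    """

    n_hours: int = 1400
    seed: int = 0
    start: str = "2021-03-01"

    # weather model
    pressure_mean: float = 1013.0   # hPa
    pressure_phi: float = 0.995
    pressure_sigma: float = 0.3     # hPa, innovation sd of the AR(1)
    temp_mean: float = 12.0         # degC
    temp_annual_amplitude: float = 8.0
    temp_diurnal_amplitude: float = 4.0
    temp_phi: float = 0.9
    temp_sigma: float = 0.6
    humidity_mean: float = 65.0     # %
    humidity_temp_coupling: float = 1.5  # % per degC, anti-correlated
    humidity_phi: float = 0.9
    humidity_sigma: float = 2.0
    wind_log_mean: float = 0.7
    wind_phi: float = 0.9
    wind_log_sigma: float = 0.2

    # radon model (scalar shorthand for the default first-order dynamics)
    target_mean: float = 130.0      # Bq/m3, long-run mean via the intercept
    radon_a1: float = -0.9
    radon_c1: float = 0.3
    radon_b: Tuple[float, float, float, float] = (-0.3, -0.25, 0.10, -1.0)
    innovation_sigma: float = 6.0   # Bq/m3
    nk: int = 1
    radon_order: Optional[ARMAXOrder] = None
    radon_params: Optional[ARMAXParameters] = None

    # planted transients (recorded weather only)
    n_transients: int = 0
    transient_channels: Tuple[str, ...] = ("temperature", "humidity")
    transient_sds: float = 10.0     # amplitude in robust SDs of the diffs
    transient_duration: int = 3     # samples

    max_rectified_fraction: float = 0.2

    def expected_inputs(self) -> Dict[str, float]:
        """Long-run mean of each weather channel."""
        wind_var = self.wind_log_sigma**2 / (1.0 - self.wind_phi**2)
        return {
            "pressure": self.pressure_mean,
            "temperature": self.temp_mean,
            "humidity": self.humidity_mean,
            "wind": float(np.exp(self.wind_log_mean + wind_var / 2.0)),
        }

    def true_order(self) -> ARMAXOrder:
        if self.radon_order is not None:
            return self.radon_order
        return ARMAXOrder(na=1, nb=(1, 1, 1, 1), nc=1, nk=self.nk)

    def true_parameters(self) -> ARMAXParameters:
        """The generating model, intercept solved for the target mean."""
        if self.radon_params is not None:
            return self.radon_params
        order = self.true_order()
        b = {
            ch: np.array([g])
            for ch, g, nbi in zip(CHANNELS, self.radon_b, order.nb)
            if nbi > 0
        }
        params = ARMAXParameters(
            a=np.array([self.radon_a1])[: order.na],
            b=b,
            c=np.array([self.radon_c1])[: order.nc],
            intercept=0.0,
            noise_variance=self.innovation_sigma**2,
        )
        eu = self.expected_inputs()
        a1 = float(np.sum(params.a_poly))
        mu = self.target_mean * a1 - sum(
            params.b_gain(ch) * eu[ch] for ch in params.b
        )
        params.intercept = float(mu)
        return params


@dataclass
class Transient:
    channel: str
    start: int
    duration: int
    amplitude: float

    @property
    def samples(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.duration)


@dataclass
class GroundTruth:
    """Everything needed to score an estimator against the generator."""

    order: ARMAXOrder
    params: ARMAXParameters
    transients: List[Transient]
    true_period_mean: float     # realized mean of the generated radon series
    analytic_mean: float        # steady-state mean at expected weather
    rectified_fraction: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "order": {
                "na": self.order.na,
                "nb": list(self.order.nb),
                "nc": self.order.nc,
                "nk": self.order.nk,
            },
            "params": self.params.to_dict(),
            "transients": [
                {
                    "channel": tr.channel,
                    "start": tr.start,
                    "duration": tr.duration,
                    "amplitude": tr.amplitude,
                }
                for tr in self.transients
            ],
            "true_period_mean": self.true_period_mean,
            "analytic_mean": self.analytic_mean,
            "rectified_fraction": self.rectified_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            order=ARMAXOrder(
                na=d["order"]["na"],
                nb=tuple(d["order"]["nb"]),
                nc=d["order"]["nc"],
                nk=d["order"]["nk"],
            ),
            params=ARMAXParameters.from_dict(d["params"]),
            transients=[
                Transient(t["channel"], t["start"], t["duration"], t["amplitude"])
                for t in d["transients"]
            ],
            true_period_mean=float(d["true_period_mean"]),
            analytic_mean=float(d["analytic_mean"]),
            rectified_fraction=float(d["rectified_fraction"]),
            seed=int(d["seed"]),
        )


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary zero-mean AR(1) realisation."""
    eps = rng.normal(0.0, sigma, n)
    x0 = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    zi = signal.lfiltic([1.0], [1.0, -phi], y=[x0])
    x, _ = signal.lfilter([1.0], [1.0, -phi], eps, zi=zi)
    return x


def inject_transients(
    bundle: SeriesBundle,
    positions: Sequence[int],
    amplitudes: Sequence[float],
    channel: str,
    duration: int = 3,
) -> SeriesBundle:
    """Add square-pulse steps to one recorded weather channel.

    Each transient raises (or lowers) the channel by its amplitude over
    ``[pos, pos + duration)`` and returns to baseline afterwards, so the
    first difference at the onset index equals the amplitude.
    """
    if channel not in CHANNELS:
        raise ParameterError(f"unknown channel {channel!r}")
    if len(positions) != len(amplitudes):
        raise ParameterError("positions and amplitudes must pair up")
    if duration < 1:
        raise ParameterError("duration must be >= 1")
    pos = sorted(int(p) for p in positions)
    for p in pos:
        if not 1 <= p <= bundle.n - duration:
            raise ParameterError(f"transient at {p} outside the series")
    for p, q in zip(pos, pos[1:]):
        if q < p + duration + 1:
            raise ParameterError(f"transients at {p} and {q} overlap")
    out = bundle.copy()
    x = out.channel(channel)
    for p, amp in sorted(zip((int(p) for p in positions), amplitudes)):
        x[p : p + duration] += amp
    return out


def _robust_diff_sd(x: np.ndarray) -> float:
    d = np.diff(x[np.isfinite(x)])
    med = np.median(d)
    return float(MAD_SCALE * np.median(np.abs(d - med)))


def generate(config: ScenarioConfig = ScenarioConfig()) -> Tuple[SeriesBundle, GroundTruth]:
    """Generate one scenario: weather first, then radon from the true ARMAX.

    Reproducible from ``config.seed``.  Raises :class:`ScenarioError` when
    the configuration is infeasible (too few samples for the true parameter
    count, or rectification beyond ``max_rectified_fraction`` — advise a
    larger target mean).
    """
    order = config.true_order()
    params = config.true_parameters()
    n = config.n_hours
    if n < 10 * order.n_params():
        raise ScenarioError(
            f"n_hours={n} < 10 x {order.n_params()} true parameters"
        )
    rng = np.random.default_rng(config.seed)
    t = np.arange(n, dtype=float)
    start_ts = pd.Timestamp(config.start)
    t0 = (start_ts.dayofyear - 1) * 24 + start_ts.hour

    pressure = config.pressure_mean + _ar1(
        rng, n, config.pressure_phi, config.pressure_sigma
    )
    temperature = (
        config.temp_mean
        - config.temp_annual_amplitude * np.cos(2 * np.pi * (t + t0) / HOURS_PER_YEAR)
        + config.temp_diurnal_amplitude * np.sin(2 * np.pi * t / 24.0)
        + _ar1(rng, n, config.temp_phi, config.temp_sigma)
    )
    humidity = np.clip(
        config.humidity_mean
        - config.humidity_temp_coupling * (temperature - config.temp_mean)
        + _ar1(rng, n, config.humidity_phi, config.humidity_sigma),
        20.0,
        100.0,
    )
    wind = np.exp(config.wind_log_mean + _ar1(rng, n, config.wind_phi, config.wind_log_sigma))

    exog = {
        "pressure": pressure,
        "temperature": temperature,
        "humidity": humidity,
        "wind": wind,
    }
    analytic_mean = params.steady_state(config.expected_inputs())
    innovations = rng.normal(0.0, np.sqrt(params.noise_variance), n)
    radon = simulate_free_run(
        params,
        order,
        {ch: exog[ch] for ch in order.used_channels},
        y_init=np.full(order.na, analytic_mean) if order.na else None,
        noise=innovations,
        n_samples=n,
        pad_inputs=True,
    )
    rectified = radon < 0
    fraction = float(np.mean(rectified))
    if fraction > config.max_rectified_fraction:
        raise ScenarioError(
            f"{fraction:.0%} of generated radon samples were negative; "
            "increase target_mean or reduce gains/noise"
        )
    radon = np.maximum(radon, 0.0)

    bundle = SeriesBundle(
        index=pd.date_range(start_ts, periods=n, freq="1h"),
        radon=radon,
        mask=np.ones(n, dtype=bool),
        sampling_interval=pd.Timedelta("1h"),
        **exog,
    ).validate()

    transients: List[Transient] = []
    if config.n_transients > 0:
        dur = config.transient_duration
        taken: List[int] = []
        margin = dur + 6
        lo, hi = 48, n - 48 - dur
        if hi <= lo:
            raise ScenarioError("series too short to place transients")
        tries = 0
        while len(taken) < config.n_transients:
            p = int(rng.integers(lo, hi))
            if all(abs(p - q) >= margin for q in taken):
                taken.append(p)
            tries += 1
            if tries > 1000 * config.n_transients:
                raise ScenarioError("cannot place non-overlapping transients")
        taken.sort()
        per_channel: Dict[str, List[Tuple[int, float]]] = {}
        for k, p in enumerate(taken):
            ch = config.transient_channels[k % len(config.transient_channels)]
            amp = config.transient_sds * _robust_diff_sd(bundle.channel(ch))
            if amp == 0:
                raise ScenarioError(f"channel {ch!r} has zero diff spread")
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if ch == "humidity":  # keep the recorded channel physical
                base = bundle.humidity[p : p + dur].max()
                if base + amp > 100.0:
                    sign = -1.0
                elif bundle.humidity[p : p + dur].min() - amp < 0.0:
                    sign = 1.0
            per_channel.setdefault(ch, []).append((p, sign * amp))
            transients.append(Transient(ch, p, dur, sign * amp))
        out = bundle
        for ch, items in per_channel.items():
            out = inject_transients(
                out,
                [p for p, _ in items],
                [a for _, a in items],
                ch,
                duration=dur,
            )
        bundle = out
        bundle.humidity[:] = np.clip(bundle.humidity, 0.0, 100.0)
        bundle.validate()

    truth = GroundTruth(
        order=order,
        params=params,
        transients=transients,
        true_period_mean=float(np.mean(radon)),
        analytic_mean=float(analytic_mean),
        rectified_fraction=fraction,
        seed=config.seed,
    )
    return bundle, truth
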