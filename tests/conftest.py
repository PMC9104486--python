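"""Shared fixtures: bundle builders and seeded Monte-Carlo panels.

The heavy seeded panels are session-scoped so that module-level property
tests and the acceptance tests share one computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
import pytest

import radonarmax as rx

warnings.simplefilter("ignore", rx.UnstableModelWarning)


def make_bundle(
    radon,
    pressure=None,
    temperature=None,
    humidity=None,
    wind=None,
    mask=None,
    start="2021-03-01",
    interval="1h",
) -> rx.SeriesBundle:
    """Assemble a bundle from plain arrays (zeros for missing channels)."""
    radon = np.asarray(radon, dtype=float)
    n = radon.size

    def arr(x):
        return np.zeros(n) if x is None else np.asarray(x, dtype=float)

    return rx.SeriesBundle(
        index=pd.date_range(start, periods=n, freq=interval),
        radon=radon,
        pressure=arr(pressure),
        temperature=arr(temperature),
        humidity=arr(humidity),
        wind=arr(wind),
        mask=np.ones(n, dtype=bool) if mask is None else np.asarray(mask, bool),
        sampling_interval=interval,
    )


# ---------------------------------------------------------------------------
# study conditions frozen for the seeded panels

SMALL_GRID = rx.OrderGrid(max_na=1, max_nb=(1, 1, 1, 1), max_nc=1)

#: order-recovery scenario: first-order pressure-driven radon dynamics
RECOVERY_ORDER = rx.ARMAXOrder(na=1, nb=(1, 0, 0, 0), nc=1)
RECOVERY_PARAMS = rx.ARMAXParameters(
    a=[-0.7], b={"pressure": [-2.0]}, c=[0.3],
    intercept=0.3 * 120 + 2.0 * 1013, noise_variance=16.0,
)
RECOVERY_N, RECOVERY_H, RECOVERY_SEEDS = 1500, 500, 50

CONTAMINATED = dict(n_hours=1000, n_transients=8, transient_sds=12.0, transient_duration=4)
CONTAMINATED_H = 600

COVERAGE_N, COVERAGE_H, COVERAGE_BOOT = 8760, 1000, 200


@dataclass
class RecoveryPanel:
    hits: int
    within_10pct: int
    n_seeds: int


@pytest.fixture(scope="session")
def order_recovery_panel() -> RecoveryPanel:
    """NET selection over the full 3^6 grid on data of known order."""
    grid = rx.OrderGrid(max_na=2, max_nb=(2, 2, 2, 2), max_nc=2)
    true_idx = (1, 1, 0, 0, 0, 1)
    hits = within = 0
    for seed in range(RECOVERY_SEEDS):
        cfg = rx.ScenarioConfig(
            n_hours=RECOVERY_N, seed=seed,
            radon_order=RECOVERY_ORDER, radon_params=RECOVERY_PARAMS,
        )
        bundle, _ = rx.generate(cfg)
        res = rx.net_select(bundle, rx.SplitConfig(RECOVERY_H), grid)
        hits += res.best_index == true_idx
        true_sse = res.sse[true_idx]
        within += abs(res.sse[res.best_index] - true_sse) <= 0.1 * true_sse
    return RecoveryPanel(hits=hits, within_10pct=within, n_seeds=RECOVERY_SEEDS)


@pytest.fixture(scope="session")
def estimator_mc_errors() -> List[float]:
    """|a1 error| per seed for y(t)=0.7y(t-1)+u(t-1)+e(t)+0.4e(t-1), n=2000."""
    order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=1)
    params = rx.ARMAXParameters(a=[-0.7], b={"temperature": [1.0]}, c=[0.4])
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 2000
        u = rng.normal(0, 1, n)
        e = rng.normal(0, 1, n)
        y = rx.simulate_free_run(params, order, {"temperature": u}, noise=e)
        bundle = make_bundle(y, temperature=u)
        fit = rx.estimate_pem(bundle, order)
        errs.append(abs(fit.params.a[0] + 0.7))
    return errs


@pytest.fixture(scope="session")
def bias_trend_panel() -> Dict[int, List[float]]:
    """|relative bias| per seed at h=400 and h=1000, default scenario."""
    out: Dict[int, List[float]] = {400: [], 1000: []}
    for seed in range(20):
        bundle, _ = rx.generate(rx.ScenarioConfig(n_hours=1400, seed=seed))
        for h in (400, 1000):
            res = rx.run_pipeline(bundle, rx.SplitConfig(h), SMALL_GRID)
            out[h].append(abs(res.report.relative_bias))
    return out


@pytest.fixture(scope="session")
def seed7_benchmark() -> Dict[int, float]:
    """Relative bias at h in {400, 600, 800, 1000} for the seed-7 scenario."""
    bundle, _ = rx.generate(rx.ScenarioConfig(n_hours=1400, seed=7))
    return {
        h: rx.run_pipeline(bundle, rx.SplitConfig(h), SMALL_GRID).report.relative_bias
        for h in (400, 600, 800, 1000)
    }


@pytest.fixture(scope="session")
def fit_trend_panel() -> Dict[int, List[float]]:
    """fit_percent per seed at h in {100, 200, 400, 800}."""
    out: Dict[int, List[float]] = {h: [] for h in (100, 200, 400, 800)}
    for seed in range(100, 120):
        bundle, _ = rx.generate(rx.ScenarioConfig(n_hours=1200, seed=seed))
        for h in out:
            res = rx.run_pipeline(bundle, rx.SplitConfig(h), SMALL_GRID)
            out[h].append(res.report.fit_percent)
    return out


@pytest.fixture(scope="session")
def flattening_panel() -> List[float]:
    """|bias| with flattening minus |bias| without, per seed, on
    transient-contaminated scenarios (negative = flattening helped)."""
    deltas = []
    for seed in range(20):
        bundle, _ = rx.generate(rx.ScenarioConfig(seed=seed, **CONTAMINATED))
        split = rx.SplitConfig(CONTAMINATED_H)
        raw = rx.run_pipeline(bundle, split, SMALL_GRID)
        flat = rx.run_pipeline(bundle, split, SMALL_GRID, flatten_config=rx.FlattenConfig())
        deltas.append(abs(flat.report.relative_bias) - abs(raw.report.relative_bias))
    return deltas


@pytest.fixture(scope="session")
def coverage_panel() -> List[bool]:
    """Whether the 95% annual-mean CI covers the generator truth, per seed."""
    covered = []
    for seed in range(20):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=COVERAGE_N, seed=seed))
        split = rx.SplitConfig(COVERAGE_H)
        fit = rx.estimate_pem(bundle, truth.order, split)
        exog = {ch: bundle.channel(ch) for ch in truth.order.used_channels}
        est = rx.extrapolate_period_mean(
            fit, exog, n_boot=COVERAGE_BOOT, seed=seed, creation=(bundle, split)
        )
        lo, hi = est.ci
        covered.append(lo <= truth.true_period_mean <= hi)
    return covered
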