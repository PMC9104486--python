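"""Time-aligned radon / weather series and CSV log I/O.

The central container is :class:`SeriesBundle`: an hourly (or otherwise
uniformly sampled) grid carrying the measured radon activity concentration
(Bq/m3) together with the four exogenous meteorological channels that drive
indoor radon dynamics — barometric pressure (hPa), outdoor temperature (degC),
relative humidity (%) and wind speed (m/s) — plus a per-sample validity mask.
Raw monitor and weather-station logs rarely share a grid, so they are read
into ragged :class:`SeriesFragment` objects and merged with :func:`align`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    ParameterError,
)

#: Exogenous channel names, in canonical order (P, T, U, W).
CHANNELS: Tuple[str, ...] = ("pressure", "temperature", "humidity", "wind")

#: Single-letter aliases used by the CLI and in compact configs.
CHANNEL_LETTERS: Dict[str, str] = {
    "P": "pressure",
    "T": "temperature",
    "U": "humidity",
    "W": "wind",
}

UNITS: Dict[str, str] = {
    "radon": "Bq/m3",
    "pressure": "hPa",
    "temperature": "degC",
    "humidity": "%",
    "wind": "m/s",
}

#: Built-in column-name maps.  Monitor export formats vary, so the dialect is
#: just a mapping from canonical channel names to CSV column headers; any
#: channel may be omitted (it is then absent from the fragment).
DIALECTS: Dict[str, Dict[str, str]] = {
    "generic": {
        "time": "time",
        "radon": "radon",
        "pressure": "pressure",
        "temperature": "temperature",
        "humidity": "humidity",
        "wind": "wind",
    },
    # Columns as exported by a typical continuous-monitor logging utility.
    "alphaguard": {
        "time": "Time",
        "radon": "Radon [Bq/m3]",
        "pressure": "Pressure [hPa]",
        "temperature": "Temperature [degC]",
        "humidity": "Humidity [%]",
        "wind": "Wind [m/s]",
    },
}


def _resolve_dialect(dialect) -> Dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ParameterError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    return dict(dialect)


@dataclass
class SeriesFragment:
    """A ragged, possibly non-uniform set of timestamped channels.

    Fragments are what the readers return; :func:`align` turns fragments into
    a uniform :class:`SeriesBundle`.  Invalid samples are NaN.
    """

    index: pd.DatetimeIndex
    channels: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.index = pd.DatetimeIndex(self.index)
        if len(self.index) == 0:
            raise EmptyInputError("fragment has no samples")
        order = np.argsort(self.index.asi8, kind="stable")
        idx = self.index[order]
        keep = np.ones(len(idx), dtype=bool)
        keep[1:] = np.diff(idx.asi8) > 0  # drop duplicate stamps, keep first
        self.index = idx[keep]
        self.channels = {
            k: np.asarray(v, dtype=float)[order][keep] for k, v in self.channels.items()
        }
        for k, v in self.channels.items():
            if v.shape != (len(self.index),):
                raise ParameterError(f"channel {k!r} length mismatch")

    @property
    def n(self) -> int:
        return len(self.index)

    def native_interval(self) -> pd.Timedelta:
        """Median spacing of the fragment's timestamps."""
        if self.n < 2:
            raise ParameterError("cannot infer interval from a single sample")
        return pd.Timedelta(np.median(np.diff(self.index.asi8)), unit="ns")


def _parse_times(raw: pd.Series, path) -> pd.DatetimeIndex:
    if pd.api.types.is_numeric_dtype(raw):
        stamps = pd.to_datetime(raw, unit="s", errors="coerce")
    else:
        stamps = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = stamps.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"{path}: unparseable timestamp on line {line}: {raw[bad].iloc[0]!r}")
    if stamps.isna().any():
        line = int(np.flatnonzero(stamps.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: missing timestamp on line {line}")
    return pd.DatetimeIndex(stamps)


def _read_log(path, dialect, wanted) -> SeriesFragment:
    d = _resolve_dialect(dialect)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    tcol = d.get("time", "time")
    if tcol not in df.columns:
        raise FormatError(f"{path}: missing timestamp column {tcol!r}")
    idx = _parse_times(df[tcol], path)
    channels: Dict[str, np.ndarray] = {}
    for name in wanted:
        col = d.get(name)
        if col is None or col not in df.columns:
            continue
        # Non-numeric cells become NaN (invalid-masked after alignment).
        channels[name] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    if not channels:
        raise FormatError(f"{path}: none of the expected channels {wanted} found")
    return SeriesFragment(idx, channels)


def read_radon_log(path, dialect="generic") -> SeriesFragment:
    """Read a continuous-radon-monitor CSV export (radon channel only)."""
    return _read_log(path, dialect, ("radon",))


def read_weather_log(path, dialect="generic") -> SeriesFragment:
    """Read a weather-station CSV log (any of the P, T, U, W channels).

    Channels that the dialect maps to a missing/absent column are simply not
    present in the fragment; after :func:`align` they appear as all-NaN
    (invalid) channels.
    """
    return _read_log(path, dialect, CHANNELS)


@dataclass
class SeriesBundle:
    """Uniformly sampled, time-aligned radon + weather series.

    ``mask`` is the per-timestamp validity flag: flattening and gap policies
    clear it, regression only uses samples inside contiguous valid runs.
    Channels that were never observed are all-NaN and do not participate in
    the mask.
    """

    index: pd.DatetimeIndex
    radon: np.ndarray
    pressure: np.ndarray
    temperature: np.ndarray
    humidity: np.ndarray
    wind: np.ndarray
    mask: np.ndarray
    sampling_interval: pd.Timedelta

    def __post_init__(self) -> None:
        self.index = pd.DatetimeIndex(self.index)
        for name in ("radon",) + CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sampling_interval = pd.Timedelta(self.sampling_interval)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> "SeriesBundle":
        n = len(self.index)
        for name in ("radon",) + CHANNELS + ("mask",):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"channel {name!r} length != {n}")
        if n >= 2:
            step = self.sampling_interval.value
            if step <= 0 or not np.all(np.diff(self.index.asi8) == step):
                raise ParameterError("timestamps are not a uniform grid at sampling_interval")
        ok = self.mask & np.isfinite(self.radon)
        if np.any(self.radon[ok] < -1e-9):
            raise ParameterError("negative radon concentration in valid samples")
        okh = self.mask & np.isfinite(self.humidity)
        if np.any((self.humidity[okh] < -1e-9) | (self.humidity[okh] > 100 + 1e-9)):
            raise ParameterError("humidity outside [0, 100] in valid samples")
        return self

    # -- accessors ----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.index)

    def channel(self, name: str) -> np.ndarray:
        if name not in ("radon",) + CHANNELS:
            raise ParameterError(f"unknown channel {name!r}")
        return getattr(self, name)

    def exog(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def present_channels(self) -> Tuple[str, ...]:
        return tuple(c for c in CHANNELS if np.isfinite(getattr(self, c)).any())

    def copy(self) -> "SeriesBundle":
        return SeriesBundle(
            self.index.copy(),
            *(getattr(self, c).copy() for c in ("radon",) + CHANNELS),
            self.mask.copy(),
            self.sampling_interval,
        )

    def with_mask(self, mask: np.ndarray) -> "SeriesBundle":
        out = self.copy()
        out.mask = np.asarray(mask, dtype=bool).copy()
        return out

    # -- (de)serialization --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.index.map(lambda t: t.isoformat())})
        for name in ("radon",) + CHANNELS:
            df[name] = getattr(self, name)
        df["mask"] = self.mask.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SeriesBundle":
        idx = _parse_times(df["time"], "<frame>")
        if len(idx) >= 2:
            interval = pd.Timedelta(int(np.diff(idx.asi8)[0]), unit="ns")
        else:
            interval = pd.Timedelta("1h")
        kwargs = {}
        for name in ("radon",) + CHANNELS:
            if name in df.columns:
                kwargs[name] = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
            else:
                kwargs[name] = np.full(len(idx), np.nan)
        mask = (
            df["mask"].to_numpy().astype(bool)
            if "mask" in df.columns
            else np.ones(len(idx), dtype=bool)
        )
        return cls(idx, mask=mask, sampling_interval=interval, **kwargs).validate()

    def split_fragments(self) -> Tuple[SeriesFragment, SeriesFragment]:
        """Decompose into (radon, weather) fragments, e.g. to re-align."""
        radon = SeriesFragment(self.index, {"radon": self.radon.copy()})
        weather = SeriesFragment(
            self.index, {c: getattr(self, c).copy() for c in self.present_channels()}
        )
        return radon, weather


@dataclass(frozen=True)
class SplitConfig:
    """Boundary between the creation (learning) and validation windows.

    Samples ``t < h`` are the creation window used to estimate parameters;
    samples ``t >= h`` are the validation window the model is verified on.
    """

    h: int

    def validate(self, n: int) -> "SplitConfig":
        if not 0 < self.h < n:
            raise ParameterError(f"split h={self.h} must satisfy 0 < h < {n}")
        return self


# ---------------------------------------------------------------------------
# alignment


def _resample_channel(
    idx: pd.DatetimeIndex,
    values: np.ndarray,
    grid: pd.DatetimeIndex,
    target: pd.Timedelta,
    native: pd.Timedelta,
    gap_limit: int,
) -> np.ndarray:
    """Project one observed channel onto the target grid.

    Downsampling (native <= target): mean over each half-open target bin
    labelled by its left edge.  Upsampling (native > target): linear
    interpolation between observations, but only across holes no wider than
    ``(gap_limit + 1) * max(native, target)`` — longer gaps stay NaN.
    """
    ok = np.isfinite(values)
    if not ok.any():
        return np.full(len(grid), np.nan)
    t_obs = idx.asi8[ok].astype(float)
    v_obs = values[ok]
    t_grid = grid.asi8.astype(float)
    out = np.full(len(grid), np.nan)

    if native > target:  # upsample by interpolation
        inside = (t_grid >= t_obs[0]) & (t_grid <= t_obs[-1])
        out[inside] = np.interp(t_grid[inside], t_obs, v_obs)
        # mask grid points whose bracketing observations are too far apart
        limit = (gap_limit + 1) * max(native.value, target.value)
        right = np.searchsorted(t_obs, t_grid, side="left")
        for i in np.flatnonzero(inside):
            r = right[i]
            if r == 0 or t_obs[min(r, len(t_obs) - 1)] == t_grid[i]:
                continue
            if t_obs[r] - t_obs[r - 1] > limit:
                out[i] = np.nan
        return out

    # downsample: bin means, bins anchored at the grid start
    start = grid.asi8[0]
    bins = (idx.asi8[ok] - start) // target.value
    keep = (bins >= 0) & (bins < len(grid))
    bins = bins[keep].astype(int)
    if len(bins) == 0:
        return out
    sums = np.bincount(bins, weights=v_obs[keep], minlength=len(grid))
    counts = np.bincount(bins, minlength=len(grid))
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def align(
    radon: SeriesFragment,
    weather: SeriesFragment,
    target_interval="1h",
    gap_limit: int = 3,
) -> SeriesBundle:
    """Merge radon and weather fragments onto a common uniform grid.

    The grid is anchored at the later of the two fragment starts and covers
    only the temporal overlap.  Each channel is mean-aggregated when its
    native cadence is finer than the target and linearly interpolated (across
    holes of at most ``gap_limit`` samples) when coarser.  Samples where any
    observed channel is NaN end up invalid-masked.
    """
    target = pd.Timedelta(target_interval)
    if target <= pd.Timedelta(0):
        raise ParameterError("target_interval must be positive")
    start = max(radon.index[0], weather.index[0])
    end = min(radon.index[-1], weather.index[-1])
    if end - start < 2 * target:
        raise AlignmentError(
            f"fragments overlap for {end - start} < 2 x target interval {target}"
        )
    grid = pd.date_range(start, end, freq=target)

    data: Dict[str, np.ndarray] = {}
    for frag in (radon, weather):
        native = frag.native_interval() if frag.n >= 2 else target
        for name, vals in frag.channels.items():
            data[name] = _resample_channel(frag.index, vals, grid, target, native, gap_limit)

    arrays = {
        name: data.get(name, np.full(len(grid), np.nan)) for name in ("radon",) + CHANNELS
    }
    present = [name for name, arr in arrays.items() if np.isfinite(arr).any()]
    mask = np.ones(len(grid), dtype=bool)
    for name in present:
        mask &= np.isfinite(arrays[name])
    return SeriesBundle(
        grid, mask=mask, sampling_interval=target, **arrays
    ).validate()


# ---------------------------------------------------------------------------
# bundle CSV round-trip


def write_bundle(bundle: SeriesBundle, path) -> None:
    """Write a bundle as CSV: ISO-8601 timestamps, one column per channel,
    plus a 0/1 mask column.  Full float precision (lossless round-trip)."""
    bundle.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_bundle(path) -> SeriesBundle:
    """Read back a CSV written by :func:`write_bundle`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return SeriesBundle.from_frame(df)
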