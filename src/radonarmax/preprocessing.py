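"""Input pre-treatment: moving average, cut filters, and flattening.

Flattening is the removal of time intervals in which the meteorological
inputs show abrupt variations (sensor glitches, local disturbances) that the
indoor radon signal does not follow.  Such intervals act as noise on the
regression: masking them out stabilises the fitted model at the cost of some
usable data.  Detection is a modified z-score (median/MAD) test on first
differences, computed within contiguous valid runs so that existing holes do
not create spurious "jumps".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .errors import ParameterError
from .series_io import CHANNELS, SeriesBundle

#: MAD -> standard-deviation consistency constant for normal data.
MAD_SCALE = 1.4826


def valid_runs(valid: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open ``(start, end)`` spans of consecutive True entries."""
    valid = np.asarray(valid, dtype=bool)
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def moving_average(
    values: Sequence[float], window: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    Masked (or NaN) samples are excluded from every window's mean; positions
    whose window contains no valid sample come back NaN.
    """
    x = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ParameterError(f"window {window} larger than series length {x.size}")
    valid = np.isfinite(x)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    filled = np.where(valid, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    return out


def cut_filter(
    values: Sequence[float],
    kind: str,
    cutoff: float,
    mask: np.ndarray | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth cut filter.

    ``kind="high-cut"`` is a low-pass (suppresses fast oscillations),
    ``kind="low-cut"`` a high-pass (suppresses slow drift); ``cutoff`` is in
    cycles per sample, 0 < cutoff < 0.5.  Forward-backward filtering keeps
    the series in phase with its timestamps.  Each contiguous valid run is
    filtered independently; runs too short for the filter transient are
    returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if not 0.0 < cutoff < 0.5:
        raise ParameterError(f"cutoff must be in (0, 0.5) cycles/sample, got {cutoff}")
    if kind not in ("high-cut", "low-cut"):
        raise ParameterError(f"kind must be 'high-cut' or 'low-cut', got {kind!r}")
    btype = "lowpass" if kind == "high-cut" else "highpass"
    b, a = signal.butter(order, cutoff, btype=btype, fs=1.0)
    padlen = 3 * max(len(a), len(b))
    valid = np.isfinite(x)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    out = x.copy()
    for s, e in valid_runs(valid):
        if e - s > padlen:
            out[s:e] = signal.filtfilt(b, a, x[s:e])
    return out


@dataclass(frozen=True)
class FlattenConfig:
    """Parameters of the abrupt-variation screen.

    ``z_threshold`` is a modified z-score cutoff on first differences (3.5 is
    the classic outlier cutoff); ``guard`` samples on each side of a flagged
    sample are removed with it; ``channels`` restricts screening to a subset
    of the meteorological inputs.
    """

    z_threshold: float = 3.5
    guard: int = 2
    channels: Tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ParameterError("z_threshold must be > 0")
        if self.guard < 0:
            raise ParameterError("guard must be >= 0")
        for c in self.channels:
            if c not in CHANNELS:
                raise ParameterError(f"unknown channel {c!r}")


def flatten(
    bundle: SeriesBundle, config: FlattenConfig = FlattenConfig()
) -> Tuple[SeriesBundle, List[Tuple[int, int]]]:
    """Mask out intervals where screened inputs vary abruptly.

    For each screened channel, first differences are taken inside contiguous
    valid runs; sample ``t`` is flagged when
    ``|d(t) - median(d)| / (1.4826 * MAD(d)) > z_threshold`` where
    ``d(t) = x(t) - x(t-1)``.  Flagged samples plus ``guard`` neighbours on
    each side are invalidated across *all* channels (a removed interval
    removes the whole time slice).  If MAD is zero the test degenerates:
    samples with a nonzero deviation are flagged (infinite z), and with
    all-equal differences nothing is flagged.

    Returns the updated bundle and the removed intervals as half-open
    ``(start, end)`` index pairs.  Flattening only ever shrinks the valid
    set.
    """
    flagged = np.zeros(bundle.n, dtype=bool)
    for name in config.channels:
        x = bundle.channel(name)
        valid = bundle.mask & np.isfinite(x)
        for s, e in valid_runs(valid):
            if e - s < 3:
                continue
            d = np.diff(x[s:e])
            med = np.median(d)
            mad = np.median(np.abs(d - med))
            dev = np.abs(d - med)
            if mad > 0:
                z = dev / (MAD_SCALE * mad)
            else:
                z = np.where(dev > 0, np.inf, 0.0)
            hits = np.flatnonzero(z > config.z_threshold)
            # d[j] is the transition into sample s + j + 1
            flagged[s + hits + 1] = True

    removed = np.zeros(bundle.n, dtype=bool)
    for t in np.flatnonzero(flagged):
        lo = max(0, t - config.guard)
        hi = min(bundle.n, t + config.guard + 1)
        removed[lo:hi] = True

    intervals = valid_runs(removed)
    out = bundle.with_mask(bundle.mask & ~removed)
    return out, intervals
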