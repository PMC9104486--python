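"""ARMAX model: representation, prediction, simulation, PEM estimation.

The model for the radon concentration ``y(t)`` driven by the meteorological
inputs ``u_i(t)`` (pressure, temperature, humidity, wind) is

    A(q) y(t) = mu + SUM_i B_i(q) u_i(t) + C(q) e(t)

with monic ``A(q) = 1 + a_1 q^-1 + ... + a_na q^-na`` and
``C(q) = 1 + c_1 q^-1 + ... + c_nc q^-nc``, input polynomials
``B_i(q) = b_{i,1} q^-nk + ... + b_{i,nb_i} q^-(nk+nb_i-1)`` sharing a common
dead time ``nk`` (default 1: inputs act from the previous sample), and an
explicit constant load term ``mu`` that absorbs the indoor radon baseline
(soil-gas entry that does not vary with the weather channels).

Parameters are estimated by the prediction-error method: minimise the sum of
squared one-step-ahead prediction errors with a two-stage initialisation
(long-ARX fit for residual estimates, then linear least squares including the
residual regressors) followed by damped Gauss-Newton refinement.  C(q) is
projected back inside the unit circle (invertibility) at every step; A(q) is
*not* constrained — an unstable fit is reported, not rejected.

Masked samples split the record into contiguous valid runs; no regression
vector ever spans a hole, the residual recursion restarts at zero in each
run, and the first max-lag samples of each run are excluded from the loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .errors import (
    CoverageError,
    DegeneracyError,
    InsufficientDataError,
    ParameterError,
    UnstableModelWarning,
)
from .preprocessing import valid_runs
from .series_io import CHANNELS, SeriesBundle, SplitConfig

MODEL_SCHEMA = "radon-armax/model-v1"


# ---------------------------------------------------------------------------
# structural orders and coefficients


@dataclass(frozen=True)
class ARMAXOrder:
    """The six structural degrees of freedom plus the input dead time.

    ``na``: AR order of A(q); ``nb``: per-channel order of B_i(q), in
    canonical (P, T, U, W) order; ``nc``: MA order of C(q); ``nk``: dead time
    in samples, applied to every input.
    """

    na: int
    nb: Tuple[int, int, int, int]
    nc: int
    nk: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.nb, Mapping):
            nb = tuple(int(self.nb.get(c, 0)) for c in CHANNELS)
            object.__setattr__(self, "nb", nb)
        else:
            nb = tuple(int(v) for v in self.nb)
            if len(nb) != len(CHANNELS):
                raise ParameterError(f"nb must have {len(CHANNELS)} entries, got {nb}")
            object.__setattr__(self, "nb", nb)
        if self.na < 0 or self.nc < 0 or any(v < 0 for v in self.nb):
            raise ParameterError("orders must be >= 0")
        if self.nk < 1:
            raise ParameterError("dead time nk must be >= 1")
        if self.na == 0 and self.nc == 0 and all(v == 0 for v in self.nb):
            raise ParameterError("at least one of na, nb, nc must be > 0")

    @property
    def nb_map(self) -> Dict[str, int]:
        return dict(zip(CHANNELS, self.nb))

    @property
    def used_channels(self) -> Tuple[str, ...]:
        return tuple(c for c, v in zip(CHANNELS, self.nb) if v > 0)

    @property
    def max_lag(self) -> int:
        lags = [self.na, self.nc]
        lags += [self.nk + v - 1 for v in self.nb if v > 0]
        return max(lags)

    def n_params(self, fit_intercept: bool = True) -> int:
        return self.na + sum(self.nb) + self.nc + int(fit_intercept)

    def as_indices(self) -> Tuple[int, int, int, int, int, int]:
        """(na, nb_P, nb_T, nb_U, nb_W, nc) — the grid-cell coordinates."""
        return (self.na, *self.nb, self.nc)


@dataclass
class ARMAXParameters:
    """Coefficients of A(q), B_i(q), C(q) plus intercept and noise variance."""

    a: np.ndarray
    b: Dict[str, np.ndarray]
    c: np.ndarray
    intercept: float = 0.0
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if self.a.size == 0:
            self.a = np.zeros(0)
        if self.c.size == 0:
            self.c = np.zeros(0)
        self.b = {
            ch: np.atleast_1d(np.asarray(v, dtype=float))
            for ch, v in self.b.items()
            if np.atleast_1d(v).size > 0
        }
        if self.noise_variance < 0:
            raise ParameterError("noise_variance must be >= 0")

    @property
    def a_poly(self) -> np.ndarray:
        return np.concatenate(([1.0], self.a))

    @property
    def c_poly(self) -> np.ndarray:
        return np.concatenate(([1.0], self.c))

    def b_gain(self, channel: str) -> float:
        """B_i(1): static gain numerator of one input channel."""
        return float(np.sum(self.b.get(channel, 0.0)))

    def steady_state(self, u_const: Mapping[str, float]) -> float:
        """DC response ``(mu + SUM B_i(1) u_i) / A(1)`` to constant inputs."""
        num = self.intercept + sum(
            self.b_gain(ch) * float(u_const.get(ch, 0.0)) for ch in self.b
        )
        den = float(np.sum(self.a_poly))
        return num / den

    @property
    def is_stable(self) -> bool:
        if self.a.size == 0:
            return True
        return bool(np.all(np.abs(np.roots(self.a_poly)) < 1.0))

    @property
    def is_invertible(self) -> bool:
        if self.c.size == 0:
            return True
        return bool(np.all(np.abs(np.roots(self.c_poly)) < 1.0))

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "b": {ch: v.tolist() for ch, v in self.b.items()},
            "c": self.c.tolist(),
            "intercept": self.intercept,
            "noise_variance": self.noise_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ARMAXParameters":
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b={ch: np.asarray(v, dtype=float) for ch, v in d["b"].items()},
            c=np.asarray(d["c"], dtype=float),
            intercept=float(d["intercept"]),
            noise_variance=float(d["noise_variance"]),
        )


@dataclass
class FitResult:
    """Outcome of a PEM fit.

    ``residuals`` is a full-length series (NaN outside the fitted rows) and
    ``loss`` equals the sum of its squares over the fitted samples.
    """

    params: ARMAXParameters
    order: ARMAXOrder
    residuals: Optional[np.ndarray]
    loss: float
    iterations: int
    converged: bool
    n_samples: int = 0


# ---------------------------------------------------------------------------
# model JSON round-trip


def save_model(fit: FitResult, path) -> None:
    doc = {
        "schema": MODEL_SCHEMA,
        "order": {
            "na": fit.order.na,
            "nb": list(fit.order.nb),
            "nc": fit.order.nc,
            "nk": fit.order.nk,
        },
        "params": fit.params.to_dict(),
        "fit": {
            "loss": fit.loss,
            "iterations": fit.iterations,
            "converged": fit.converged,
            "n_samples": fit.n_samples,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> FitResult:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != MODEL_SCHEMA:
        raise ParameterError(f"unexpected model schema {doc.get('schema')!r}")
    order = ARMAXOrder(
        na=doc["order"]["na"],
        nb=tuple(doc["order"]["nb"]),
        nc=doc["order"]["nc"],
        nk=doc["order"]["nk"],
    )
    params = ARMAXParameters.from_dict(doc["params"])
    meta = doc["fit"]
    return FitResult(
        params=params,
        order=order,
        residuals=None,
        loss=float(meta["loss"]),
        iterations=int(meta["iterations"]),
        converged=bool(meta["converged"]),
        n_samples=int(meta["n_samples"]),
    )


# ---------------------------------------------------------------------------
# regression machinery


def _theta_layout(order: ARMAXOrder, fit_intercept: bool):
    na, nc = order.na, order.nc
    nb_sum = sum(order.nb)
    ia = slice(0, na)
    ib = slice(na, na + nb_sum)
    ic = slice(na + nb_sum, na + nb_sum + nc)
    size = na + nb_sum + nc + int(fit_intercept)
    return ia, ib, ic, size


def pack_theta(params: ARMAXParameters, order: ARMAXOrder, fit_intercept: bool = True):
    parts = [np.zeros(order.na), ]
    parts[0][: params.a.size] = params.a[: order.na]
    for ch, nbi in zip(CHANNELS, order.nb):
        if nbi:
            col = np.zeros(nbi)
            src = params.b.get(ch, np.zeros(0))
            col[: min(nbi, src.size)] = src[:nbi]
            parts.append(col)
    cpart = np.zeros(order.nc)
    cpart[: min(order.nc, params.c.size)] = params.c[: order.nc]
    parts.append(cpart)
    if fit_intercept:
        parts.append(np.array([params.intercept]))
    return np.concatenate(parts) if parts else np.zeros(0)


def unpack_theta(
    theta: np.ndarray,
    order: ARMAXOrder,
    fit_intercept: bool = True,
    noise_variance: float = 0.0,
) -> ARMAXParameters:
    ia, ib, ic, size = _theta_layout(order, fit_intercept)
    b: Dict[str, np.ndarray] = {}
    off = ib.start
    for ch, nbi in zip(CHANNELS, order.nb):
        if nbi:
            b[ch] = theta[off : off + nbi].copy()
            off += nbi
    return ARMAXParameters(
        a=theta[ia].copy(),
        b=b,
        c=theta[ic].copy(),
        intercept=float(theta[-1]) if fit_intercept else 0.0,
        noise_variance=noise_variance,
    )


def _fit_rows(valid: np.ndarray, maxlag: int, stop: int):
    """Row indices usable for regression, grouped into contiguous segments.

    Returns (rows, bounds): ``rows`` is the concatenated index array and
    ``bounds`` the half-open (i0, i1) spans of each segment *in row
    coordinates* (for restarting the residual recursion).
    """
    rows_parts: List[np.ndarray] = []
    bounds: List[Tuple[int, int]] = []
    off = 0
    for s, e in valid_runs(valid[:stop]):
        lo = s + maxlag
        if lo >= e:
            continue
        rows_parts.append(np.arange(lo, e))
        bounds.append((off, off + e - lo))
        off += e - lo
    if not rows_parts:
        return np.zeros(0, dtype=int), []
    return np.concatenate(rows_parts), bounds


def _lag_cols(x: np.ndarray, rows: np.ndarray, lags: np.ndarray) -> np.ndarray:
    if lags.size == 0:
        return np.zeros((rows.size, 0))
    return x[rows[:, None] - lags[None, :]]


def _filter_segments(x: np.ndarray, c_poly: np.ndarray, bounds) -> np.ndarray:
    """Apply 1/C(q) (zero initial state) independently on each segment."""
    if c_poly.size == 1:
        return x.copy()
    out = np.empty_like(x)
    for i0, i1 in bounds:
        out[i0:i1] = signal.lfilter([1.0], c_poly, x[i0:i1], axis=0)
    return out


def _project_invertible(c: np.ndarray) -> np.ndarray:
    """Reflect roots of C(q) on/outside the unit circle to the inside."""
    if c.size == 0:
        return c
    roots = np.roots(np.concatenate(([1.0], c)))
    mags = np.abs(roots)
    if np.all(mags < 1.0 - 1e-9):
        return c
    roots = np.where(mags >= 1.0 - 1e-9, (1.0 - 1e-6) / np.conj(roots), roots)
    poly = np.real(np.poly(roots))
    return poly[1:] / poly[0]


def _bundle_valid(bundle: SeriesBundle, order: ARMAXOrder) -> np.ndarray:
    valid = bundle.mask & np.isfinite(bundle.radon)
    for ch in order.used_channels:
        valid &= np.isfinite(bundle.channel(ch))
    return valid


def _check_rank(X: np.ndarray, order: ARMAXOrder, bundle: SeriesBundle, rows) -> None:
    if X.shape[1] == 0:
        return
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] > s[0] * 1e-10:
        return
    for ch in order.used_channels:
        u = bundle.channel(ch)[rows]
        if np.ptp(u[np.isfinite(u)]) == 0:
            raise DegeneracyError(
                f"input channel {ch!r} is constant over the creation window: "
                f"B_{ch} coefficients are not identifiable"
            )
    raise DegeneracyError("rank-deficient regression matrix")


def _stage1_residuals(
    y: np.ndarray,
    bundle: SeriesBundle,
    order: ARMAXOrder,
    valid: np.ndarray,
    stop: int,
) -> np.ndarray:
    """Long-ARX residual estimates (Hannan-Rissanen stage 1), full-length,
    zero outside the long-ARX rows."""
    used = order.used_channels
    p = max(10, 2 * (order.na + order.nc))
    eps = np.zeros(y.size)
    while p >= 1:
        maxlag = max(p, order.nk + p - 1)
        rows, _ = _fit_rows(valid, maxlag, stop)
        ncols = p * (1 + len(used)) + 1
        if rows.size >= 2 * ncols:
            ylags = np.arange(1, p + 1)
            cols = [-_lag_cols(y, rows, ylags)]
            for ch in used:
                cols.append(
                    _lag_cols(bundle.channel(ch), rows, np.arange(order.nk, order.nk + p))
                )
            cols.append(np.ones((rows.size, 1)))
            X = np.hstack(cols)
            theta, *_ = np.linalg.lstsq(X, y[rows], rcond=None)
            eps[rows] = y[rows] - X @ theta
            return eps
        p //= 2
    return eps


def estimate_pem(
    bundle: SeriesBundle,
    order: ARMAXOrder,
    split: Optional[SplitConfig] = None,
    *,
    fit_intercept: bool = True,
    max_iter: int = 200,
    tol: float = 1e-9,
    sample_factor: float = 10.0,
) -> FitResult:
    """Prediction-error estimate of the ARMAX parameters.

    Only the creation window (``t < split.h``) is used when ``split`` is
    given.  Raises :class:`InsufficientDataError` when fewer than
    ``sample_factor`` x (parameter count) valid regression rows exist, and
    :class:`DegeneracyError` on a rank-deficient regression.
    """
    n = bundle.n
    stop = split.validate(n).h if split is not None else n
    y = bundle.radon
    valid = _bundle_valid(bundle, order)
    maxlag = order.max_lag
    rows, bounds = _fit_rows(valid, maxlag, stop)
    npar = order.n_params(fit_intercept)
    if rows.size < sample_factor * npar:
        raise InsufficientDataError(
            f"creation window provides {rows.size} usable samples; "
            f"need >= {sample_factor:g} x {npar} parameters"
        )

    na, nc, nk = order.na, order.nc, order.nk
    y_rows = y[rows]
    Yl = -_lag_cols(y, rows, np.arange(1, na + 1))
    u_blocks = [
        _lag_cols(bundle.channel(ch), rows, np.arange(nk, nk + nbi))
        for ch, nbi in zip(CHANNELS, order.nb)
        if nbi
    ]
    Ub = np.hstack(u_blocks) if u_blocks else np.zeros((rows.size, 0))
    One = np.ones((rows.size, 1)) if fit_intercept else np.zeros((rows.size, 0))
    ia, ib, ic, size = _theta_layout(order, fit_intercept)

    _check_rank(np.hstack([Yl, Ub, One]), order, bundle, rows)

    def v_of(theta: np.ndarray) -> np.ndarray:
        v = y_rows - Yl @ theta[ia] - Ub @ theta[ib]
        if fit_intercept:
            v = v - theta[-1]
        return v

    def loss_eps(theta: np.ndarray):
        c_poly = np.concatenate(([1.0], theta[ic]))
        eps = _filter_segments(v_of(theta), c_poly, bounds)
        return eps, float(eps @ eps)

    if nc == 0:
        X = np.hstack([Yl, Ub, One])
        theta, *_ = np.linalg.lstsq(X, y_rows, rcond=None)
        eps = y_rows - X @ theta
        loss = float(eps @ eps)
        iterations, converged = 0, True
    else:
        eps0_full = _stage1_residuals(y, bundle, order, valid, stop)
        El0 = _lag_cols(eps0_full, rows, np.arange(1, nc + 1))
        X2 = np.hstack([Yl, Ub, El0, One])
        try:
            theta, *_ = np.linalg.lstsq(X2, y_rows, rcond=None)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DegeneracyError(str(exc)) from exc
        theta[ic] = _project_invertible(theta[ic])
        eps, loss = loss_eps(theta)

        iterations, converged = 0, False
        eps_full = np.zeros(n)
        for it in range(1, max_iter + 1):
            iterations = it
            c_poly = np.concatenate(([1.0], theta[ic]))
            eps_full[:] = 0.0
            eps_full[rows] = eps
            El = _lag_cols(eps_full, rows, np.arange(1, nc + 1))
            Phi = np.hstack([Yl, Ub, El, One])
            Psi = np.empty_like(Phi)
            for i0, i1 in bounds:
                Psi[i0:i1] = signal.lfilter([1.0], c_poly, Phi[i0:i1], axis=0)
            try:
                step, *_ = np.linalg.lstsq(Psi, eps, rcond=None)
            except np.linalg.LinAlgError:
                break
            improved = False
            alpha = 1.0
            for _ in range(16):
                cand = theta + alpha * step
                cand[ic] = _project_invertible(cand[ic])
                eps_c, loss_c = loss_eps(cand)
                if loss_c < loss:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                converged = True  # no descent direction left: at a PEM optimum
                break
            rel = (loss - loss_c) / max(loss, 1e-300)
            theta, eps, loss = cand, eps_c, loss_c
            if rel < tol or loss <= 1e-20 * rows.size:
                converged = True
                break

    noise_variance = loss / max(rows.size - npar, 1)
    params = unpack_theta(theta, order, fit_intercept, noise_variance)
    residuals = np.full(n, np.nan)
    residuals[rows] = eps
    return FitResult(
        params=params,
        order=order,
        residuals=residuals,
        loss=loss,
        iterations=iterations,
        converged=converged,
        n_samples=int(rows.size),
    )


# ---------------------------------------------------------------------------
# prediction and simulation


def one_step_predictions(
    params: ARMAXParameters,
    order: ARMAXOrder,
    bundle: SeriesBundle,
    split: Optional[SplitConfig] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predictions and residuals, NaN where undefined."""
    n = bundle.n
    stop = split.validate(n).h if split is not None else n
    y = bundle.radon
    valid = _bundle_valid(bundle, order)
    rows, bounds = _fit_rows(valid, order.max_lag, stop)
    yhat = np.full(n, np.nan)
    eps = np.full(n, np.nan)
    if rows.size == 0:
        return yhat, eps
    theta = pack_theta(params, order, fit_intercept=True)
    theta[-1] = params.intercept
    Yl = -_lag_cols(y, rows, np.arange(1, order.na + 1))
    u_blocks = [
        _lag_cols(bundle.channel(ch), rows, np.arange(order.nk, order.nk + nbi))
        for ch, nbi in zip(CHANNELS, order.nb)
        if nbi
    ]
    Ub = np.hstack(u_blocks) if u_blocks else np.zeros((rows.size, 0))
    ia, ib, ic, _ = _theta_layout(order, True)
    v = y[rows] - Yl @ theta[ia] - Ub @ theta[ib] - params.intercept
    e = _filter_segments(v, params.c_poly, bounds)
    eps[rows] = e
    yhat[rows] = y[rows] - e
    return yhat, eps


def predict_one_step(
    params: ARMAXParameters, order: ARMAXOrder, bundle: SeriesBundle, t: int
) -> float:
    """Predict y(t) from measured history (and recursively formed residuals)."""
    yhat, _ = one_step_predictions(params, order, bundle)
    if not 0 <= t < bundle.n or not np.isfinite(yhat[t]):
        raise InsufficientDataError(
            f"insufficient valid history to form the regression vector at t={t}"
        )
    return float(yhat[t])


def simulate_free_run(
    params: ARMAXParameters,
    order: ARMAXOrder,
    exog: Mapping[str, np.ndarray],
    y_init: Optional[Sequence[float]] = None,
    noise: Optional[np.ndarray] = None,
    start: int = 0,
    n_samples: Optional[int] = None,
    pad_inputs: bool = False,
) -> np.ndarray:
    """Free-run simulation: the recursion uses its own simulated outputs.

    ``exog`` maps channel names to arrays on a common global index; the
    simulation covers ``t in [start, N)`` and is returned as an array of
    length ``N - start``.  Output lags before ``start`` come from ``y_init``
    (the ``na`` values immediately preceding ``start``, chronological order;
    zeros when omitted); input lags before index 0 are taken as zero, or as
    the channel's first value with ``pad_inputs=True`` (use the latter to
    start a simulation in statistical equilibrium rather than from rest).
    With ``noise`` omitted the innovations are identically zero
    (deterministic simulation); otherwise ``noise`` supplies e(t) for the
    simulated span.
    """
    used = order.used_channels
    if used:
        missing = [ch for ch in used if ch not in exog]
        if missing:
            raise ParameterError(f"exogenous channels missing: {missing}")
        lengths = {len(np.asarray(exog[ch])) for ch in used}
        if len(lengths) != 1:
            raise ParameterError("exogenous channels have unequal lengths")
        n = lengths.pop()
    else:
        if n_samples is None and noise is not None:
            n_samples = start + len(noise)
        if n_samples is None:
            raise ParameterError("n_samples required when the model uses no inputs")
        n = n_samples
    if not 0 <= start < n:
        raise ParameterError(f"start={start} outside [0, {n})")
    horizon = n - start

    if not params.is_stable:
        warnings.warn(
            "A(q) has roots on or outside the unit circle; free-run simulation "
            "may diverge",
            UnstableModelWarning,
            stacklevel=2,
        )

    v = np.full(horizon, float(params.intercept))
    for ch in used:
        u = np.asarray(exog[ch], dtype=float)
        lo = max(0, start - (order.nk + order.nb_map[ch] - 1))
        if not np.all(np.isfinite(u[lo:n])):
            raise CoverageError(f"exogenous channel {ch!r} has gaps over the horizon")
        coeffs = params.b.get(ch, np.zeros(order.nb_map[ch]))
        for j, bj in enumerate(coeffs):
            lag = order.nk + j
            i0 = start - lag
            if i0 >= 0:
                seg = u[i0 : n - lag]
            else:
                fill = u[0] if pad_inputs else 0.0
                seg = np.concatenate((np.full(-i0, fill), u[0 : n - lag]))
            v += bj * seg

    if noise is not None:
        e = np.asarray(noise, dtype=float)
        if e.shape != (horizon,):
            raise ParameterError(f"noise must have length {horizon}")
        v = v + signal.lfilter(params.c_poly, [1.0], e)

    if order.na == 0:
        return v
    seed = np.zeros(order.na)
    if y_init is not None:
        y0 = np.asarray(y_init, dtype=float)
        if y0.size < order.na:
            raise ParameterError(f"y_init must provide >= {order.na} seed values")
        seed = y0[-order.na :]
    zi = signal.lfiltic([1.0], params.a_poly, y=seed[::-1])
    y, _ = signal.lfilter([1.0], params.a_poly, v, zi=zi)
    return y


def _interp_fill(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid samples; edges hold nearest."""
    ok = valid & np.isfinite(x)
    if not ok.any():
        raise CoverageError("channel has no valid samples to interpolate from")
    idx = np.arange(x.size)
    return np.interp(idx, idx[ok], x[ok])


def free_run_window(
    params: ARMAXParameters,
    order: ARMAXOrder,
    bundle: SeriesBundle,
    start: int,
    stop: Optional[int] = None,
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Free-run simulation over ``[start, stop)`` seeded with measured data.

    The output recursion is seeded with the last ``na`` measured radon values
    before ``start`` (nearest valid sample substituted for masked ones) and
    the exogenous inputs are taken from the bundle with masked samples
    linearly interpolated, so one continuous simulation spans the window.
    """
    stop = bundle.n if stop is None else stop
    if not 0 < start < stop <= bundle.n:
        raise ParameterError(f"window [{start}, {stop}) invalid for n={bundle.n}")
    exog = {
        ch: _interp_fill(bundle.channel(ch)[:stop], bundle.mask[:stop])
        for ch in order.used_channels
    }
    y_init = None
    if order.na > 0:
        yv = bundle.radon
        ok = bundle.mask & np.isfinite(yv)
        seed = np.empty(order.na)
        for j, t in enumerate(range(start - order.na, start)):
            if 0 <= t < bundle.n and ok[t]:
                seed[j] = yv[t]
            else:
                prev = np.flatnonzero(ok[: max(t, 0) + 1])
                if prev.size:
                    seed[j] = yv[prev[-1]]
                else:
                    nxt = np.flatnonzero(ok)
                    seed[j] = yv[nxt[0]]
        y_init = seed
    return simulate_free_run(
        params, order, exog, y_init=y_init, noise=noise, start=start,
        n_samples=stop,
    )
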