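"""Exhaustive grid search over the six structural orders (NET selection).

The structural order of the model — (n_a, n_b_P, n_b_T, n_b_U, n_b_W, n_c) —
is chosen by brute force: every combination up to a per-index maximum is
fitted on the creation window and scored by free-run simulation over the
validation window.  The default score is the sum of squared differences
between the simulated and measured concentration (the squared area between
the two curves); the alternative ``mean_match`` score is the absolute
difference of their means.  All scores are recorded in a six-dimensional
matrix; the selected cell is its argmin, with ties broken toward the
smaller total parameter count and then the lexicographically smallest index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .armax_core import ARMAXOrder, FitResult, estimate_pem, free_run_window
from .errors import RadonArmaxError, ParameterError, SearchFailureError
from .series_io import CHANNELS, SeriesBundle, SplitConfig

log = logging.getLogger(__name__)

CRITERIA = ("sse", "mean_match")


@dataclass(frozen=True)
class OrderGrid:
    """Maximum degree per free index; the grid spans all combinations."""

    max_na: int = 3
    max_nb: Tuple[int, int, int, int] = (3, 3, 3, 3)
    max_nc: int = 3
    nk: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.max_nb, dict):
            object.__setattr__(
                self, "max_nb", tuple(int(self.max_nb.get(c, 0)) for c in CHANNELS)
            )
        else:
            object.__setattr__(self, "max_nb", tuple(int(v) for v in self.max_nb))
        if len(self.max_nb) != len(CHANNELS):
            raise ParameterError(f"max_nb needs {len(CHANNELS)} entries")
        if self.max_na < 0 or self.max_nc < 0 or any(v < 0 for v in self.max_nb):
            raise ParameterError("maximum orders must be >= 0")
        if self.nk < 1:
            raise ParameterError("nk must be >= 1")

    @property
    def shape(self) -> Tuple[int, ...]:
        return (self.max_na + 1, *(v + 1 for v in self.max_nb), self.max_nc + 1)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def cells(self) -> Iterator[Tuple[Tuple[int, ...], Optional[ARMAXOrder]]]:
        """Lexicographic iteration; the all-zero cell yields order None."""
        for idx in itertools.product(*(range(s) for s in self.shape)):
            na, nbp, nbt, nbu, nbw, nc = idx
            if na == 0 and nc == 0 and nbp == nbt == nbu == nbw == 0:
                yield idx, None
                continue
            yield idx, ARMAXOrder(na=na, nb=(nbp, nbt, nbu, nbw), nc=nc, nk=self.nk)


def window_scores(measured, simulated) -> Tuple[float, float]:
    """Both NET scores for a measured/simulated window pair.

    Returns ``(sse, mean_match)``: the squared area between the two curves
    and the absolute difference of their means.
    """
    meas = np.asarray(measured, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if meas.shape != sim.shape or meas.size < 1:
        raise ParameterError("windows must have equal length >= 1")
    diff = sim - meas
    return float(diff @ diff), float(abs(np.mean(sim) - np.mean(meas)))


def _window_scores(
    bundle: SeriesBundle, split: SplitConfig, fit: FitResult
) -> Tuple[float, float, np.ndarray]:
    """Validation-window free-run scores for a fitted model."""
    sim = free_run_window(fit.params, fit.order, bundle, start=split.h)
    meas = bundle.radon[split.h :]
    ok = bundle.mask[split.h :] & np.isfinite(meas)
    if not ok.any():
        raise SearchFailureError("no valid samples in the validation window")
    sse, mean_match = window_scores(meas[ok], sim[ok])
    return sse, mean_match, sim


def score_order(
    bundle: SeriesBundle,
    split: SplitConfig,
    order: ARMAXOrder,
    criterion: str = "sse",
    **fit_kwargs,
) -> float:
    """Fit one order on the creation window and score it on validation.

    Returns ``+inf`` when the fit is infeasible.
    """
    if criterion not in CRITERIA:
        raise ParameterError(f"criterion must be one of {CRITERIA}")
    try:
        fit = estimate_pem(bundle, order, split, **fit_kwargs)
        sse, mean_match, _ = _window_scores(bundle, split, fit)
    except RadonArmaxError as exc:
        log.debug("order %s infeasible: %s", order, exc)
        return float("inf")
    return sse if criterion == "sse" else mean_match


@dataclass
class OrderSearchResult:
    """Full score matrix plus the selected cell.

    ``sse`` and ``mean_match`` hold both criteria for every cell (failed
    fits are ``+inf``); ``scores`` is the matrix of the criterion that drove
    the selection.
    """

    grid: OrderGrid
    criterion: str
    sse: np.ndarray
    mean_match: np.ndarray
    best_index: Tuple[int, ...]
    best_order: ARMAXOrder
    best_fit: FitResult
    failures: Dict[Tuple[int, ...], str] = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return self.sse if self.criterion == "sse" else self.mean_match

    def to_table(self) -> pd.DataFrame:
        """One row per order combination: the six indices plus both scores."""
        recs = []
        for idx in itertools.product(*(range(s) for s in self.grid.shape)):
            recs.append(
                (*idx, float(self.sse[idx]), float(self.mean_match[idx]))
            )
        return pd.DataFrame(
            recs,
            columns=["na", "nb_P", "nb_T", "nb_U", "nb_W", "nc", "sse", "mean_match"],
        )


def net_select(
    bundle: SeriesBundle,
    split: SplitConfig,
    grid: OrderGrid,
    criterion: str = "sse",
    **fit_kwargs,
) -> OrderSearchResult:
    """Evaluate every order combination and select the best cell.

    The creation window (``t < h``) estimates each candidate's parameters;
    the validation window (``t >= h``) scores its free-run simulation.  The
    argmin of the chosen criterion is returned together with the full score
    matrix; exact ties go to the smaller total parameter count, then to the
    lexicographically smallest index, so the selection does not depend on
    iteration order.
    """
    if criterion not in CRITERIA:
        raise ParameterError(f"criterion must be one of {CRITERIA}")
    split.validate(bundle.n)
    shape = grid.shape
    sse = np.full(shape, np.inf)
    mean_match = np.full(shape, np.inf)
    fits: Dict[Tuple[int, ...], FitResult] = {}
    failures: Dict[Tuple[int, ...], str] = {}

    for idx, order in grid.cells():
        if order is None:
            failures[idx] = "all orders zero"
            continue
        try:
            fit = estimate_pem(bundle, order, split, **fit_kwargs)
            cell_sse, cell_mm, _ = _window_scores(bundle, split, fit)
        except RadonArmaxError as exc:
            failures[idx] = str(exc)
            continue
        sse[idx] = cell_sse
        mean_match[idx] = cell_mm
        fits[idx] = fit

    primary = sse if criterion == "sse" else mean_match
    finite = np.isfinite(primary)
    if not finite.any():
        raise SearchFailureError(
            f"all {grid.size} order combinations failed to fit; "
            f"first cause: {next(iter(failures.values()), 'unknown')}"
        )
    best_val = primary[finite].min()
    candidates = [idx for idx in fits if primary[idx] == best_val]
    best_index = min(candidates, key=lambda idx: (sum(idx), idx))
    return OrderSearchResult(
        grid=grid,
        criterion=criterion,
        sse=sse,
        mean_match=mean_match,
        best_index=best_index,
        best_order=fits[best_index].order,
        best_fit=fits[best_index],
        failures=failures,
    )
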