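"""Exhaustive exponent-grid sweep and the SSE accuracy surface.

For every exponent pair (a, b) on a discrete grid with a < b <= b_max, the
coefficients (p, q) are fitted repeatedly from two randomly chosen timepoints
by Cramer's rule, each candidate is scored by the sum of squared errors of the
predicted growth rate against the finite-difference gradient targets over
*all* timepoints, and the best of the trials is kept. The map
(a, b) -> min-trial SSE is the accuracy surface: its low-SSE valley is the
region of exponent space worth exploring with more expensive methods.

Grid points are generated from integer indices (a = i*step, b = j*step,
i < j), never by accumulating floating-point increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NoFitError
from .trajectories import GradientSeries, Trajectory

__all__ = [
    "GridSpec",
    "FitResult",
    "AccuracySurface",
    "make_grid",
    "fit_pair",
    "sweep_surface",
    "best_fit",
]

SURFACE_COLUMNS = ["a", "b", "p", "q", "sse", "n_failed_trials"]


@dataclass(frozen=True)
class GridSpec:
    """Exponent-grid specification.

    step : exponent increment (paper default 0.01).
    b_max : upper bound on the decay exponent (default 3.0).
    a_min : lower bound on the growth exponent; defaults to ``step``.
    region_filter : optional predicate (a, b) -> bool applied to each pair,
        e.g. ``lambda a, b: a > 1.0 and b > 1.0`` for the recovery region.
    """

    step: float = 0.01
    b_max: float = 3.0
    a_min: Optional[float] = None
    region_filter: Optional[Callable[[float, float], bool]] = None

    def __post_init__(self):
        if not self.step > 0:
            raise ConfigurationError(f"step must be positive, got {self.step}")
        a_min = self.step if self.a_min is None else self.a_min
        if a_min < self.step:
            raise ConfigurationError(f"a_min ({a_min}) must be >= step ({self.step})")
        if not self.b_max > a_min:
            raise ConfigurationError(
                f"b_max ({self.b_max}) must exceed a_min ({a_min})"
            )
        object.__setattr__(self, "a_min", a_min)

    def indices(self) -> list[tuple[int, int]]:
        """Integer index pairs (i, j), i < j, with a = i*step, b = j*step."""
        i_min = int(np.ceil(self.a_min / self.step - 1e-9))
        j_max = int(np.floor(self.b_max / self.step + 1e-9))
        out = []
        for i in range(i_min, j_max):
            a = i * self.step
            for j in range(i + 1, j_max + 1):
                b = j * self.step
                if self.region_filter is not None and not self.region_filter(a, b):
                    continue
                out.append((i, j))
        return out


def make_grid(spec: GridSpec) -> np.ndarray:
    """All exponent pairs of the grid, lexicographically ordered, shape (n, 2)."""
    idx = spec.indices()
    if not idx:
        raise ConfigurationError(f"grid spec {spec!r} produces an empty grid")
    arr = np.asarray(idx, dtype=float) * spec.step
    return arr


@dataclass(frozen=True)
class FitResult:
    """Best-of-trials Cramer fit at one exponent pair.

    ``win_idx`` holds the two timepoint indices of the winning trial (None if
    every trial failed); ``trial_sses`` is retained only when requested.
    """

    a: float
    b: float
    p: float
    q: float
    sse: float
    n_failed_trials: int
    win_idx: Optional[tuple[int, int]] = None
    trial_sses: Optional[np.ndarray] = field(default=None, compare=False)

    @property
    def params(self):
        from .bp import BPParams

        return BPParams(self.p, self.q, self.a, self.b)


def _draw_distinct_pairs(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """``size`` index pairs, each two distinct timepoints uniform without replacement."""
    first = rng.integers(0, n, size=size)
    second = rng.integers(0, n - 1, size=size)
    second = second + (second >= first)
    return np.column_stack([first, second])


def fit_pair(
    traj: Trajectory,
    grads: GradientSeries,
    a: float,
    b: float,
    trials: int = 20,
    rng: Optional[np.random.Generator] = None,
    max_resample: int = 10,
    det_rtol: float = 1e-12,
    keep_trials: bool = False,
) -> FitResult:
    """Best-of-``trials`` Cramer fit of (p, q) at exponent pair (a, b).

    Each trial draws two distinct timepoints uniformly without replacement,
    builds the 2x2 design from (v**a, v**b), solves it exactly by Cramer's
    rule, and scores the SSE of predicted vs estimated gradients over all
    timepoints. Singular draws are resampled up to ``max_resample`` times
    within a trial; a trial still singular after that is marked failed. All
    trials are solved with the same closed-form 2x2 arithmetic
    :func:`bpsweep.cramer.cramer_solve` uses, vectorized across trials.
    """
    if trials < 1:
        raise ConfigurationError(f"trials must be >= 1, got {trials}")
    if rng is None:
        rng = np.random.default_rng()
    v = traj.volumes
    y = grads.dvdt
    n = len(v)
    va = v**a
    vb = v**b

    idx = _draw_distinct_pairs(rng, n, trials)
    i1, i2 = idx[:, 0], idx[:, 1]
    det = va[i1] * vb[i2] - vb[i1] * va[i2]
    scale = np.maximum(va[i1], va[i2]) * np.maximum(vb[i1], vb[i2])  # v > 0
    bad = np.abs(det) <= det_rtol * scale
    for _ in range(max_resample):
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        redraw = _draw_distinct_pairs(rng, n, n_bad)
        idx[bad] = redraw
        i1, i2 = idx[:, 0], idx[:, 1]
        det = va[i1] * vb[i2] - vb[i1] * va[i2]
        scale = np.maximum(va[i1], va[i2]) * np.maximum(vb[i1], vb[i2])
        bad = np.abs(det) <= det_rtol * scale

    ok = ~bad
    n_failed = int(bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = (y[i1] * vb[i2] - y[i2] * vb[i1]) / det
        c2 = (va[i1] * y[i2] - va[i2] * y[i1]) / det
    residual = c1[:, None] * va[None, :] + c2[:, None] * vb[None, :] - y[None, :]
    sse = np.einsum("ij,ij->i", residual, residual)
    sse[~ok] = np.inf

    if n_failed == trials:
        return FitResult(
            a, b, np.nan, np.nan, np.inf, n_failed,
            win_idx=None, trial_sses=sse if keep_trials else None,
        )
    best = int(np.argmin(sse))
    return FitResult(
        a,
        b,
        float(c1[best]),
        float(-c2[best]),
        float(sse[best]),
        n_failed,
        win_idx=(int(idx[best, 0]), int(idx[best, 1])),
        trial_sses=sse if keep_trials else None,
    )


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    """Independent, reproducible substream for grid index (i, j)."""
    return np.random.default_rng([seed, i, j])


@dataclass
class AccuracySurface:
    """One FitResult per grid pair, with run provenance.

    ``frame`` holds columns a, b, p, q, sse, n_failed_trials in lexicographic
    (a, b) order; ``win_indices`` the winning timepoint index pairs (-1 where
    every trial failed).
    """

    frame: pd.DataFrame
    provenance: dict
    win_indices: Optional[np.ndarray] = None

    def __post_init__(self):
        pairs = self.frame[["a", "b"]].to_numpy()
        if len(np.unique(pairs, axis=0)) != len(pairs):
            raise ConfigurationError("surface contains duplicate grid pairs")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sse(self) -> np.ndarray:
        return self.frame["sse"].to_numpy()

    def result_at(self, k: int) -> FitResult:
        row = self.frame.iloc[k]
        win = None
        if self.win_indices is not None and self.win_indices[k, 0] >= 0:
            win = (int(self.win_indices[k, 0]), int(self.win_indices[k, 1]))
        return FitResult(
            float(row["a"]), float(row["b"]), float(row["p"]), float(row["q"]),
            float(row["sse"]), int(row["n_failed_trials"]), win_idx=win,
        )

    def nearest_index(self, a: float, b: float) -> int:
        """Row index of the grid pair closest (Euclidean) to (a, b)."""
        pairs = self.frame[["a", "b"]].to_numpy()
        d2 = (pairs[:, 0] - a) ** 2 + (pairs[:, 1] - b) ** 2
        return int(np.argmin(d2))

    def to_csv(self, target) -> None:
        self.frame[SURFACE_COLUMNS].to_csv(target, index=False)

    @classmethod
    def from_csv(cls, source, provenance: Optional[dict] = None) -> "AccuracySurface":
        frame = pd.read_csv(source)
        missing = set(SURFACE_COLUMNS) - set(frame.columns)
        if missing:
            raise ConfigurationError(f"surface CSV missing columns {sorted(missing)}")
        return cls(frame=frame, provenance=provenance or {})


def sweep_surface(
    traj: Trajectory,
    grads: GradientSeries,
    spec: GridSpec = GridSpec(),
    trials: int = 20,
    seed: int = 0,
    det_rtol: float = 1e-12,
) -> AccuracySurface:
    """Fit every grid pair and assemble the accuracy surface.

    Each pair uses an independent RNG substream keyed on (seed, i, j), so the
    surface is a pure, bit-reproducible function of (trajectory, spec, trials,
    seed) regardless of iteration order.
    """
    idx_pairs = spec.indices()
    if not idx_pairs:
        raise ConfigurationError(f"grid spec {spec!r} produces an empty grid")
    n = len(idx_pairs)
    out = np.empty((n, 6))
    win = np.full((n, 2), -1, dtype=int)
    for k, (i, j) in enumerate(idx_pairs):
        a, b = i * spec.step, j * spec.step
        fit = fit_pair(
            traj, grads, a, b, trials=trials, rng=_pair_rng(seed, i, j),
            det_rtol=det_rtol,
        )
        out[k] = (a, b, fit.p, fit.q, fit.sse, fit.n_failed_trials)
        if fit.win_idx is not None:
            win[k] = fit.win_idx
    frame = pd.DataFrame(out, columns=SURFACE_COLUMNS)
    frame["n_failed_trials"] = frame["n_failed_trials"].astype(int)
    provenance = {
        "seed": seed,
        "trials": trials,
        "step": spec.step,
        "b_max": spec.b_max,
        "a_min": spec.a_min,
        "n_pairs": n,
        "n_timepoints": len(traj),
    }
    return AccuracySurface(frame=frame, provenance=provenance, win_indices=win)


def best_fit(surface: AccuracySurface) -> FitResult:
    """Finite-SSE entry with minimal SSE; ties broken lexicographically in (a, b)."""
    sse = surface.sse
    finite = np.isfinite(sse)
    if not finite.any():
        raise NoFitError("every grid pair failed; surface has no finite SSE")
    # rows are lexicographic in (a, b) and argmin returns the first minimum
    masked = np.where(finite, sse, np.inf)
    return surface.result_at(int(np.argmin(masked)))
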