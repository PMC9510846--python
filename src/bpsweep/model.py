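"""Model/Results facade over the grid-sweep machinery.

`BertalanffyPutter` is constructed from a tumor-volume trajectory (arrays,
DataFrame, or CSV); its `fit` runs the exhaustive Cramer-rule exponent-grid
sweep and returns a `BPSweepResults` carrying the accuracy surface, the
best-fit parameters, diagnostics, and a text summary, with simulation and
plotting hanging off the results object.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .bp import BPParams, equilibrium_volume, simulate_bp
from .recovery import narrowing_fraction
from .sweep import AccuracySurface, FitResult, GridSpec, best_fit, sweep_surface
from .trajectories import (
    GradientSeries,
    Trajectory,
    estimate_gradients,
    read_trajectory,
)

__all__ = ["BertalanffyPutter", "BPSweepResults"]


class BertalanffyPutter:
    """Bertalanffy-Putter growth model for a tumor-volume time series.

    Parameters
    ----------
    trajectory : Trajectory
        Observed volumes at strictly increasing times (>= 3 points).
    gradients : GradientSeries, optional
        Growth-rate targets; estimated by finite differences when omitted.

    Examples
    --------
    >>> model = BertalanffyPutter.from_csv("tumor.csv")
    >>> res = model.fit(grid=GridSpec(step=0.05), trials=20, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, trajectory: Trajectory,
                 gradients: Optional[GradientSeries] = None):
        self.trajectory = trajectory
        self.gradients = gradients if gradients is not None else estimate_gradients(trajectory)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       volume_col: str = "volume") -> "BertalanffyPutter":
        return cls(Trajectory(df[time_col].to_numpy(float),
                              df[volume_col].to_numpy(float)))

    @classmethod
    def from_csv(cls, path, time_col: str = "time",
                 volume_col: str = "volume") -> "BertalanffyPutter":
        return cls(read_trajectory(path, time_col=time_col, volume_col=volume_col))

    def fit(self, grid: Optional[GridSpec] = None, trials: int = 20,
            seed: int = 0) -> "BPSweepResults":
        """Sweep the exponent grid and return the fitted results."""
        if grid is None:
            grid = GridSpec()
        surface = sweep_surface(self.trajectory, self.gradients, grid,
                                trials=trials, seed=seed)
        return BPSweepResults(self, surface)


class BPSweepResults:
    """Results of an exponent-grid sweep: surface, best fit, diagnostics."""

    def __init__(self, model: BertalanffyPutter, surface: AccuracySurface):
        self.model = model
        self.surface = surface
        self.best: FitResult = best_fit(surface)

    @property
    def params(self) -> BPParams:
        """Best-fit (p, q, a, b)."""
        return self.best.params

    @property
    def sse(self) -> float:
        return self.best.sse

    def narrowing_fraction(self, true_pair: tuple[float, float]) -> float:
        """Fraction of the grid with SSE strictly below the given pair's."""
        return narrowing_fraction(self.surface, true_pair)

    def predict(self, t_grid=None, v0: Optional[float] = None) -> Trajectory:
        """Forward-simulate the best-fit law (from the observed v0 by default)."""
        if t_grid is None:
            t_grid = self.model.trajectory.times
        if v0 is None:
            v0 = float(self.model.trajectory.volumes[0])
        return simulate_bp(self.params, v0, t_grid)

    def plot_surface(self, ax=None, **kwargs):
        from .plotting import plot_surface

        return plot_surface(self.surface, ax=ax, **kwargs)

    def save_surface(self, target) -> None:
        self.surface.to_csv(target)

    def summary(self) -> str:
        prov = self.surface.provenance
        b = self.best
        n_failed_pairs = int((~np.isfinite(self.surface.sse)).sum())
        v_eq = equilibrium_volume(b.params)
        lines = [
            "        Bertalanffy-Putter exponent-grid sweep",
            "=" * 56,
            f"No. timepoints:  {prov.get('n_timepoints', len(self.model.trajectory)):>8}"
            f"    Grid pairs:      {len(self.surface):>10}",
            f"Trials per pair: {prov.get('trials', '?'):>8}"
            f"    Seed:            {prov.get('seed', '?'):>10}",
            f"Grid step:       {prov.get('step', float('nan')):>8.3g}"
            f"    Failed pairs:    {n_failed_pairs:>10}",
            "-" * 56,
            f"Best exponents:  a = {b.a:<10.4g} b = {b.b:<10.4g}",
            f"Coefficients:    p = {b.p:<10.4g} q = {b.q:<10.4g}",
            f"SSE (gradient targets):  {b.sse:.6g}",
            f"Equilibrium volume (p/q)^(1/(b-a)):  {v_eq:.6g}",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        b = self.best
        return (f"<BPSweepResults best=(a={b.a:.4g}, b={b.b:.4g}, "
                f"p={b.p:.4g}, q={b.q:.4g}), sse={b.sse:.4g}, "
                f"n_pairs={len(self.surface)}>")
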