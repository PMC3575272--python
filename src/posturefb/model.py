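"""High-level modelling interface.

:class:`StanceBiofeedbackModel` bundles reference trajectories, scenario
templates and a free-parameter list into one fittable object whose
``fit()`` runs the two-stage pipeline — optional sensitivity screen,
parameter sweep, then Perpendicular Search — and returns a
:class:`StanceBiofeedbackResults` carrying the estimates, objective
value, convergence trace, per-channel validation metrics and a
``summary()`` table.  The fit is derivative-free least-squares against
averaged trajectories without a noise model, so no parameter
uncertainties are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (FitProblem, FitResult, gauss_newton_polish,
                      parameter_sweep, perpendicular_search,
                      rotating_search, sensitivity_screen)
from .simulation import Scenario, Trajectory, simulate

__all__ = ["StanceBiofeedbackModel", "StanceBiofeedbackResults"]


class StanceBiofeedbackModel:
    """Two-link stance model with additive biofeedback torque, fitted to
    reference sway/COP trajectories.

    Parameters
    ----------
    references : dict direction (deg) -> Trajectory (100-Hz grid)
    scenarios : dict direction -> Scenario template (fixed parameters)
    free_parameters : parameter paths to estimate, e.g.
        ``["controller.K_s[0,0]", "biofeedback.tau_f"]``
    bounds : optional dict path -> (lo, hi)
    sum_form : objective form, "sum-then-square" (default) or
        "sum-of-squares"
    """

    def __init__(self, references: dict[float, Trajectory],
                 scenarios: dict[float, Scenario],
                 free_parameters: list[str],
                 bounds: dict | None = None,
                 sum_form: str = "sum-then-square"):
        self.problem = FitProblem(scenarios=dict(scenarios),
                                  references=dict(references),
                                  free=list(free_parameters),
                                  bounds=dict(bounds or {}),
                                  sum_form=sum_form)

    @classmethod
    def from_problem(cls, problem: FitProblem) -> "StanceBiofeedbackModel":
        obj = cls.__new__(cls)
        obj.problem = problem
        return obj

    def objective(self, x) -> float:
        return self.problem.objective(np.asarray(x, float))

    def fit(self, sweep_grid: dict[str, list[float]] | None = None,
            screen_top: int | None = None,
            start: np.ndarray | None = None,
            search: str = "coordinate",
            polish: bool = True,
            **search_options) -> "StanceBiofeedbackResults":
        """Staged fit.

        1. optional sensitivity screen pruning the sweep grid to the
           ``screen_top`` most influential parameters;
        2. parameter sweep over ``sweep_grid`` (if given);
        3. Perpendicular Search from the best grid point —
           ``search="coordinate"`` for the cyclic coordinate scheme,
           ``"rotating"`` for the rotating-orthogonal-direction variant;
        4. Gauss-Newton polish (default on): resolves the
           correlated-parameter valley floor that direction-set schemes
           approach only slowly.
        """
        p = self.problem
        x0 = p.x0() if start is None else np.asarray(start, float)
        screen = None
        grid = sweep_grid
        if grid and screen_top is not None and screen_top < len(grid):
            screen = sensitivity_screen(p, x0)
            keep = [name for name in screen["parameter"] if name in grid]
            grid = {k: grid[k] for k in keep[:screen_top]}
        if grid:
            x0, _, sweep_table = parameter_sweep(p, grid, base=x0)
        else:
            sweep_table = None
        searcher = rotating_search if search == "rotating" \
            else perpendicular_search
        res = searcher(p, x0, **search_options)
        if polish:
            polished = gauss_newton_polish(p, res.x)
            if polished.objective <= res.objective:
                polished.trace = pd.concat(
                    [res.trace, polished.trace], ignore_index=True)
                res = polished
        return StanceBiofeedbackResults(model=self, result=res,
                                        sweep_table=sweep_table,
                                        screen=screen)


@dataclass
class StanceBiofeedbackResults:
    """Fit results: estimates, objective, diagnostics, summary table."""
    model: StanceBiofeedbackModel
    result: FitResult
    sweep_table: pd.DataFrame | None = None
    screen: pd.DataFrame | None = None

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def trace(self) -> pd.DataFrame:
        return self.result.trace

    def metrics(self) -> dict[float, list]:
        """Average error and cross-correlation per included channel and
        direction, evaluated at the fitted parameters."""
        return self.model.problem.metrics_at(self.result.x)

    def fitted_scenario(self, direction: float) -> Scenario:
        return self.model.problem.apply(self.result.x, direction)

    def simulate(self, direction: float) -> Trajectory:
        """Closed-loop trajectory at the fitted parameters."""
        return simulate(self.fitted_scenario(direction))

    def summary(self) -> str:
        lines = ["Stance-biofeedback model fit",
                 "=" * 60,
                 f"objective J        {self.objective:.6g}",
                 f"function evals     {self.result.n_evals}",
                 f"termination        {self.result.message}",
                 "",
                 "Parameter estimates",
                 "-" * 60]
        for name, value in self.params.items():
            lines.append(f"{name:<28s} {value:12.4f}")
        lines += ["", "Validation metrics (per direction / channel)",
                  "-" * 60,
                  f"{'direction':>9s} {'channel':<14s} "
                  f"{'avg error':>10s} {'xcorr':>7s}"]
        for d, res in sorted(self.metrics().items()):
            for m in res:
                lines.append(f"{d:>9.0f} {m.channel:<14s} "
                             f"{m.average_error:>10.4f} "
                             f"{m.cross_correlation:>7.3f}")
        return "\n".join(lines)
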