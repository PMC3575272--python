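"""Parameter fitting: normalized-residual objective, parameter sweep and
Perpendicular Search (cyclic coordinate descent with step halving).

The objective compares simulated AP/ML sway and COP channels against
reference trajectories over a 3-s window from perturbation onset.  Each
included channel's residual is normalized by the peak magnitude of its
reference; by default the objective integrates the *square of the sum*
of the normalized residuals (cross-terms included), with a
sum-of-squares alternative behind a switch.  Channels that the plant
cannot excite are excluded per direction: AP sway for 90-deg
perturbations and ML sway for 180-deg perturbations (the model responds
unidirectionally there), along with any channel whose reference peak is
zero.

Free parameters are addressed by path strings into the scenario, e.g.
``controller.K_s[0,1]``, ``biofeedback.tau_f``, ``biofeedback.k_s[1,0]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biofeedback import BiofeedbackParams
from .controller import ControllerParams
from .dynamics import ModelValidityError
from .metrics import MetricsResult, average_error, cross_correlation, \
    window_slice
from .simulation import Scenario, SimulationFallError, Trajectory, \
    resample_to_experiment, simulate

__all__ = ["FitProblem", "FitResult", "parameter_sweep",
           "perpendicular_search", "rotating_search",
           "gauss_newton_polish", "sensitivity_screen"]

#: fit channels: (trajectory column, plane)
FIT_CHANNELS = (("ap_sway_deg", "S"), ("ml_sway_deg", "C"),
                ("cop_x_cm", "S"), ("cop_y_cm", "C"))

_PATH_RE = re.compile(
    r"^(controller|biofeedback)\.(\w+)(?:\[(\d+)\s*,\s*(\d+)\])?$")


def _parse_path(path: str):
    m = _PATH_RE.match(path)
    if not m:
        raise ValueError(f"malformed parameter path {path!r}")
    section, attr, i, j = m.groups()
    idx = (int(i), int(j)) if i is not None else None
    return section, attr, idx


def get_param(scenario: Scenario, path: str) -> float:
    section, attr, idx = _parse_path(path)
    obj = getattr(scenario, section)
    val = getattr(obj, attr)
    return float(val[idx] if idx is not None else val)


def set_params(scenario: Scenario, updates: dict[str, float]) -> Scenario:
    """New Scenario with the addressed parameters replaced."""
    ctrl = {"K_s": np.array(scenario.controller.K_s),
            "K_c": np.array(scenario.controller.K_c),
            "t_d": scenario.controller.t_d}
    bio = {"tau_f": scenario.biofeedback.tau_f,
           "k_s": np.array(scenario.biofeedback.k_s),
           "k_c": np.array(scenario.biofeedback.k_c)}
    for path, value in updates.items():
        section, attr, idx = _parse_path(path)
        store = ctrl if section == "controller" else bio
        if attr not in store:
            raise ValueError(f"unknown parameter {path!r}")
        if idx is None:
            store[attr] = float(value)
        else:
            store[attr][idx] = float(value)
    return replace(scenario,
                   controller=ControllerParams(**ctrl),
                   biofeedback=BiofeedbackParams(**bio))


@dataclass
class FitProblem:
    """One fitting task: reference trajectories (100 Hz), per-direction
    scenario templates, the free-parameter list and bounds."""
    scenarios: dict[float, Scenario]
    references: dict[float, Trajectory]
    free: list[str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    window: float = 3.0
    sum_form: str = "sum-then-square"   # or "sum-of-squares"
    penalty: float = 1e6

    def __post_init__(self):
        if set(self.scenarios) != set(self.references):
            raise ValueError("scenarios and references must cover the same "
                             "perturbation directions")
        if self.sum_form not in ("sum-then-square", "sum-of-squares"):
            raise ValueError("sum_form must be 'sum-then-square' or "
                             "'sum-of-squares'")
        self.n_evals = 0
        self.diagnostics: list[str] = []
        self._prepare()

    def _prepare(self):
        self._refs: dict[float, dict[str, np.ndarray]] = {}
        self._norms: dict[float, dict[str, float]] = {}
        self._included: dict[float, list[str]] = {}
        for d, ref in self.references.items():
            onset = self.scenarios[d].perturbation.onset
            mask = window_slice(ref.t, onset, self.window)
            chans, norms = {}, {}
            included = []
            for col, plane in FIT_CHANNELS:
                series = ref.channel(col)[mask]
                if d == 90.0 and col == "ap_sway_deg":
                    continue            # unidirectional response: excluded
                if d == 180.0 and col == "ml_sway_deg":
                    continue
                peak = float(np.max(np.abs(series)))
                if peak <= 0:
                    continue            # unexcitable channel, nothing to fit
                chans[col] = series
                norms[col] = peak
                included.append(col)
            if not included:
                raise ValueError(f"no usable reference channels for {d} deg")
            self._refs[d] = chans
            self._norms[d] = norms
            self._included[d] = included
            self._ref_dt = ref.dt

    # -- parameter vector helpers --------------------------------------

    def x0(self) -> np.ndarray:
        sc = next(iter(self.scenarios.values()))
        return np.array([get_param(sc, p) for p in self.free])

    def project(self, x: np.ndarray) -> np.ndarray:
        """Clip into bounds and onto the k-row-ordering cone.

        A free biofeedback magnitude k[r, j] is clipped into the
        interval spanned by its row neighbours so k_1 <= k_2 <= k_3
        always holds for candidate evaluations.
        """
        x = np.array(x, float)
        for i, p in enumerate(self.free):
            if p in self.bounds:
                lo, hi = self.bounds[p]
                x[i] = min(max(x[i], lo), hi)
        sc = next(iter(self.scenarios.values()))
        for i, p in enumerate(self.free):
            section, attr, idx = _parse_path(p)
            if section != "biofeedback" or attr not in ("k_s", "k_c"):
                continue
            k = np.array(getattr(sc.biofeedback, attr))
            for jj, pp in enumerate(self.free):
                s2, a2, idx2 = _parse_path(pp)
                if s2 == "biofeedback" and a2 == attr and idx2 is not None:
                    k[idx2] = x[jj]
            r, j = idx
            lo = k[r - 1, j] if r > 0 else -np.inf
            hi = k[r + 1, j] if r < 2 else np.inf
            x[i] = min(max(x[i], lo), hi)
        return x

    def apply(self, x: np.ndarray, direction: float) -> Scenario:
        updates = dict(zip(self.free, np.asarray(x, float)))
        return set_params(self.scenarios[direction], updates)

    # -- objective -----------------------------------------------------

    def simulate_candidate(self, x, direction) -> Trajectory:
        traj = simulate(self.apply(x, direction))
        return resample_to_experiment(traj, 1.0 / self._ref_dt)

    def objective(self, x: np.ndarray) -> float:
        """Eq.-style integral objective, summed over directions."""
        total = 0.0
        for d in self.scenarios:
            try:
                sim = self.simulate_candidate(x, d)
            except (SimulationFallError, ModelValidityError) as exc:
                self.diagnostics.append(f"{d} deg @ {x}: {exc}")
                self.n_evals += 1
                return self.penalty
            onset = self.scenarios[d].perturbation.onset
            mask = window_slice(sim.t, onset, self.window)
            if self.sum_form == "sum-then-square":
                acc = None
                for col in self._included[d]:
                    r = (self._refs[d][col] - sim.channel(col)[mask]) \
                        / self._norms[d][col]
                    acc = r if acc is None else acc + r
                total += float(np.sum(acc ** 2)) * self._ref_dt
            else:
                for col in self._included[d]:
                    r = (self._refs[d][col] - sim.channel(col)[mask]) \
                        / self._norms[d][col]
                    total += float(np.sum(r ** 2)) * self._ref_dt
        self.n_evals += 1
        return total

    def residual_vector(self, x: np.ndarray) -> np.ndarray:
        """Stacked normalized residuals whose sum of squares equals J.

        For the default sum-then-square objective the residual at each
        sample is the *sum* of the included channels' normalized
        differences, scaled by sqrt(dt); for the sum-of-squares form the
        channels are stacked separately.  Used by the Gauss-Newton
        polish stage.
        """
        x = self.project(np.asarray(x, float))
        out = []
        sq = np.sqrt(self._ref_dt)
        for d in self.scenarios:
            try:
                sim = self.simulate_candidate(x, d)
            except (SimulationFallError, ModelValidityError) as exc:
                self.diagnostics.append(f"{d} deg @ {x}: {exc}")
                n = len(next(iter(self._refs[d].values())))
                out.append(np.full(n, np.sqrt(self.penalty / n)))
                continue
            onset = self.scenarios[d].perturbation.onset
            mask = window_slice(sim.t, onset, self.window)
            if self.sum_form == "sum-then-square":
                acc = None
                for col in self._included[d]:
                    r = (self._refs[d][col] - sim.channel(col)[mask]) \
                        / self._norms[d][col]
                    acc = r if acc is None else acc + r
                out.append(acc * sq)
            else:
                for col in self._included[d]:
                    r = (self._refs[d][col] - sim.channel(col)[mask]) \
                        / self._norms[d][col]
                    out.append(r * sq)
        self.n_evals += 1
        return np.concatenate(out)

    def metrics_at(self, x) -> dict[float, list[MetricsResult]]:
        out = {}
        for d in self.scenarios:
            sim = self.simulate_candidate(x, d)
            onset = self.scenarios[d].perturbation.onset
            mask = window_slice(sim.t, onset, self.window)
            res = []
            for col in self._included[d]:
                exp = self._refs[d][col]
                s = sim.channel(col)[mask]
                res.append(MetricsResult(
                    channel=col,
                    average_error=average_error(exp, s),
                    cross_correlation=cross_correlation(exp, s),
                    window=self.window))
            out[d] = res
        return out


@dataclass
class FitResult:
    """Optimal parameters, objective value and convergence trace."""
    names: list[str]
    x: np.ndarray
    objective: float
    n_evals: int
    trace: pd.DataFrame
    message: str = ""

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.x, index=self.names, name="estimate")


def parameter_sweep(problem: FitProblem,
                    grid: dict[str, list[float]],
                    base: np.ndarray | None = None
                    ) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Exhaustive evaluation over the Cartesian grid.

    ``grid`` maps free-parameter paths to level lists; parameters absent
    from the grid stay at ``base`` (default: the template values).
    Returns (best x, best J, evaluation table); ties keep the first
    point in deterministic iteration order.
    """
    unknown = set(grid) - set(problem.free)
    if unknown:
        raise ValueError(f"grid parameters not in free list: {sorted(unknown)}")
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("sweep grid must be non-empty")
    x = np.array(problem.x0() if base is None else base, float)
    keys = list(grid)
    idx = [problem.free.index(k) for k in keys]
    shapes = [len(grid[k]) for k in keys]
    best_x, best_j = None, np.inf
    records = []
    for flat in range(int(np.prod(shapes))):
        rem = flat
        cand = x.copy()
        # mixed-radix decode (first key varies slowest)
        digits = []
        for size in reversed(shapes):
            digits.append(rem % size)
            rem //= size
        digits.reverse()
        for (key, i), dgt in zip(zip(keys, idx), digits):
            cand[i] = grid[key][dgt]
        cand = problem.project(cand)
        j = problem.objective(cand)
        records.append({**{k: cand[i] for k, i in zip(keys, idx)}, "J": j})
        if j < best_j:
            best_x, best_j = cand, j
    return best_x, best_j, pd.DataFrame(records)


def perpendicular_search(problem: FitProblem,
                         start: np.ndarray,
                         initial_step: np.ndarray | float | None = None,
                         step_tol: float = 1e-3,
                         j_tol: float = 0.0,
                         max_cycles: int = 100,
                         pattern_moves: bool = True) -> FitResult:
    """Derivative-free coordinate-wise descent with step halving.

    Probes +/- the current step along each free parameter axis in turn,
    accepting improvements (and repeating an improving move along the
    same axis); when a full cycle yields no improvement all steps are
    halved.  After a successful cycle an optional pattern move (in the
    Hooke-Jeeves sense) extrapolates along the cycle's aggregate
    displacement, which accelerates progress along the correlated-gain
    valleys these objectives exhibit.  Terminates when every step falls
    below ``step_tol`` times the parameter scale, the objective reaches
    ``j_tol``, or ``max_cycles`` cycles elapse.  The k-ordering
    constraint is enforced by projection on every candidate.
    """
    x = problem.project(np.array(start, float))
    n = len(x)
    if n != len(problem.free):
        raise ValueError("start vector length must match the free list")
    scale = np.maximum(np.abs(x), 1.0)
    if initial_step is None:
        steps = 0.25 * scale
    else:
        steps = np.broadcast_to(np.asarray(initial_step, float), (n,)).copy()
    j = problem.objective(x)
    hist = [(problem.n_evals, j)]
    message = "max cycles reached"
    for cycle in range(max_cycles):
        improved = False
        x_cycle = x.copy()
        for i in range(n):
            for sgn in (1.0, -1.0):
                accepted_dir = False
                for _ in range(40):   # accelerate along a winning axis
                    cand = x.copy()
                    cand[i] += sgn * steps[i]
                    cand = problem.project(cand)
                    jc = problem.objective(cand)
                    if jc < j:
                        x, j = cand, jc
                        hist.append((problem.n_evals, j))
                        improved = True
                        accepted_dir = True
                    else:
                        break
                if accepted_dir:
                    break
        if improved and pattern_moves:
            delta = x - x_cycle
            for _ in range(25):
                cand = problem.project(x + delta)
                jc = problem.objective(cand)
                if jc < j:
                    x, j = cand, jc
                    hist.append((problem.n_evals, j))
                else:
                    break
        if j <= j_tol:
            message = "objective tolerance reached"
            break
        if not improved:
            steps /= 2.0
            if np.all(steps < step_tol * scale):
                message = "step tolerance reached"
                break
    trace = pd.DataFrame(hist, columns=["n_evals", "J"])
    return FitResult(names=list(problem.free), x=x, objective=j,
                     n_evals=problem.n_evals, trace=trace, message=message)


def rotating_search(problem: FitProblem,
                    start: np.ndarray,
                    initial_step: np.ndarray | float | None = None,
                    step_tol: float = 1e-4,
                    j_tol: float = 0.0,
                    max_evals: int = 4000,
                    expand: float = 3.0,
                    shrink: float = 0.5) -> FitResult:
    """Perpendicular search with rotating orthogonal directions
    (Rosenbrock's method).

    Like :func:`perpendicular_search` this probes one direction at a
    time with adaptive steps, but once every direction has seen both a
    success and a failure the orthogonal direction set is realigned
    (Gram-Schmidt on the accumulated displacement), which follows the
    curved, correlated-parameter valleys of trajectory-fitting
    objectives far more efficiently than fixed coordinate axes.
    Probes are projected onto bounds and the k-ordering cone.
    """
    x = problem.project(np.array(start, float))
    n = len(x)
    scale = np.maximum(np.abs(x), 1.0)
    if initial_step is None:
        step0 = 0.15 * scale
    else:
        step0 = np.broadcast_to(np.asarray(initial_step, float), (n,)).copy()
    j = problem.objective(x)
    hist = [(problem.n_evals, j)]
    D = np.eye(n)
    steps = step0.copy()
    lam = np.zeros(n)
    succeeded = np.zeros(n, bool)
    failed = np.zeros(n, bool)
    message = "max evaluations reached"
    cycles_since_rotation = 0
    while problem.n_evals < max_evals:
        for i in range(n):
            cand = problem.project(x + steps[i] * D[:, i])
            jc = problem.objective(cand)
            if jc < j:
                x, j = cand, jc
                hist.append((problem.n_evals, j))
                succeeded[i] = True
                lam[i] += steps[i]
                steps[i] *= expand
            else:
                failed[i] = True
                steps[i] *= -shrink
        if j <= j_tol:
            message = "objective tolerance reached"
            break
        cycles_since_rotation += 1
        # rotate when the classic criterion is met, or after a few
        # cycles with some progress (the strict criterion can deadlock
        # near the optimum when off-valley directions only ever fail)
        if np.any(np.abs(lam) > 0) and (np.all(succeeded & failed)
                                        or cycles_since_rotation >= 5):
            # rotate: principal direction = accumulated displacement
            A = np.zeros((n, n))
            for i in range(n):
                A[:, i] = D[:, i:] @ lam[i:]
            Q = np.zeros((n, n))
            for i in range(n):
                v = A[:, i].copy()
                for k in range(i):
                    v -= (Q[:, k] @ A[:, i]) * Q[:, k]
                nv = np.linalg.norm(v)
                Q[:, i] = v / nv if nv > 1e-14 else D[:, i]
            D = Q
            sz = np.linalg.norm(lam)
            steps = np.full(n, max(sz * 0.25, step_tol * scale.max()))
            lam = np.zeros(n)
            succeeded[:] = False
            failed[:] = False
            cycles_since_rotation = 0
        if np.all(np.abs(steps) < step_tol * scale):
            message = "step tolerance reached"
            break
    trace = pd.DataFrame(hist, columns=["n_evals", "J"])
    return FitResult(names=list(problem.free), x=x, objective=j,
                     n_evals=problem.n_evals, trace=trace, message=message)


def gauss_newton_polish(problem: FitProblem, start: np.ndarray,
                        diff_step: float = 1e-5,
                        max_nfev: int = 200) -> FitResult:
    """Levenberg-Marquardt polish of a direction-set search result.

    The objective is a (near) least-squares functional of the simulated
    trajectories, so once a derivative-free search has reached the
    correlated-parameter valley, a damped Gauss-Newton step sequence
    with a finite-difference residual Jacobian resolves the valley floor
    to machine precision in a handful of iterations — something
    coordinate schemes need thousands of probes for.  Assumes the
    optimum is interior to the bounds/ordering constraints (candidates
    are projected before simulation).
    """
    import scipy.optimize
    res = scipy.optimize.least_squares(
        problem.residual_vector, np.array(start, float), method="lm",
        diff_step=diff_step, xtol=1e-12, ftol=1e-14, gtol=1e-14,
        max_nfev=max_nfev)
    x = problem.project(res.x)
    j = problem.objective(x)
    trace = pd.DataFrame({"n_evals": [problem.n_evals], "J": [j]})
    return FitResult(names=list(problem.free), x=x, objective=j,
                     n_evals=problem.n_evals, trace=trace,
                     message=f"polish: {res.status}")


def sensitivity_screen(problem: FitProblem, base: np.ndarray,
                       deltas: np.ndarray | float = 0.1) -> pd.DataFrame:
    """One-at-a-time sensitivity of J to each free parameter.

    ``deltas`` is a relative perturbation (of the parameter scale) or a
    per-parameter array of absolute deltas.  Returns a DataFrame ranked
    by decreasing |delta J|; used to shrink sweep grids for coupled
    (e.g. 225-deg) fits.
    """
    base = problem.project(np.array(base, float))
    j0 = problem.objective(base)
    n = len(base)
    if np.isscalar(deltas):
        scale = np.maximum(np.abs(base), 1.0)
        deltas = float(deltas) * scale
    rows = []
    for i in range(n):
        cand = base.copy()
        cand[i] += deltas[i]
        jc = problem.objective(problem.project(cand))
        rows.append({"parameter": problem.free[i], "delta": deltas[i],
                     "delta_J": jc - j0, "abs_delta_J": abs(jc - j0)})
    df = pd.DataFrame(rows).sort_values(
        "abs_delta_J", ascending=False, kind="stable").reset_index(drop=True)
    return df
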