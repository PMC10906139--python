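"""Patient-specific calibration of the Fisher-Kolmogorov growth model.

:class:`TumorGrowthModel` holds a patient's scan series (measured density
maps at scan times) and a simulation grid; its :meth:`~TumorGrowthModel.fit`
estimates the diffusivity D and net proliferation rate rho by bound-
constrained Gauss-Newton minimization of the relative-L2 misfit

    J(D, rho) = sum_{i=2}^{n_s}
        int_Omega (nbar_mod(x, t_i) - nbar_meas(x, t_i))^2 dx
        / int_Omega nbar_meas(x, t_i)^2 dx,

where the model density is the forward simulation seeded with the first
scan's map.  The first scan is never fitted: it is the initial condition.
Optimization runs in log-parameter coordinates to honor the four-decade
admissible box D in [1e-6, 10] mm^2/day, rho in [1e-6, 1] 1/day, with
forward-difference Jacobians, projection onto the box, and a step-halving
line search.  The result object carries the estimates, approximate
standard errors, the iteration trace and a summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .imaging import ScanSeries
from .solver import (DensityState, GrowthParams, SimulationGrid,
                     PARAM_BOUNDS, SolverError, simulate)

__all__ = ["TumorGrowthModel", "TumorGrowthResults", "grid_search"]

INIT_D = 5e-3     # mm^2/day, calibration initial guess
INIT_RHO = 2e-3   # 1/day

FD_STEP = 1e-3            # forward-difference step in log-parameters
OBJ_RTOL = 1e-6           # relative objective change convergence criterion
MAX_ITER = 50
MAX_HALVINGS = 10


class TumorGrowthModel:
    """Fisher-Kolmogorov growth model bound to one patient's scan series.

    Parameters
    ----------
    series : ScanSeries
        Scans with strictly increasing times (days) and measured density
        maps (``series.density``); at least two scans.  Scan times are
        shifted so the first scan defines t = 0.
    grid : SimulationGrid, optional
        Masked solver grid; built from ``series.prostate`` at the given
        ``spacing``/``dt`` when omitted.
    nbar_th : float
        Density threshold defining the tumor region for derived metrics.
    """

    def __init__(self, series: ScanSeries, grid: SimulationGrid | None = None,
                 spacing: float | None = None, dt: float = 1.0,
                 nbar_th: float = 0.15,
                 bounds: tuple = PARAM_BOUNDS):
        if series.density is None:
            raise ValueError("series must carry measured density maps")
        if series.n_scans < 2:
            raise ValueError("calibration needs at least two scans")
        if grid is None:
            if spacing is None:
                raise ValueError("provide either a grid or a spacing")
            grid = SimulationGrid(series.prostate.mask, spacing, dt)
        self.series = series
        self.grid = grid
        self.nbar_th = nbar_th
        self.bounds = bounds
        # relative times: first scan defines t = 0
        self.times = series.times - series.times[0]
        self._meas = [np.asarray(d.data if hasattr(d, "data") else d,
                                 dtype=float) for d in series.density]
        self._initial = DensityState(self._meas[0], t=0.0)
        # per-scan normalizers int nbar_meas^2 dx (voxel volume cancels in J)
        self._norms = []
        for m in self._meas[1:]:
            s = float(np.sum(self.grid.pack(m) ** 2))
            if s == 0:
                raise ValueError(
                    "measured density map is identically zero at a fitted "
                    "scan time: relative misfit undefined")
            self._norms.append(s)

    # -- forward machinery -------------------------------------------------

    def simulate(self, params: GrowthParams,
                 output_times=None) -> list[DensityState]:
        """Forward-simulate from the first scan's map at the given times
        (defaults to the fitted scan times)."""
        if output_times is None:
            output_times = self.times[1:]
        return simulate(self._initial, self.grid, params,
                        np.asarray(output_times, dtype=float))

    def residuals(self, params: GrowthParams) -> np.ndarray:
        """Stacked per-voxel residuals, each scan scaled by its normalizer
        so that ``misfit = sum(residuals**2)``."""
        states = self.simulate(params)
        res = []
        for state, meas, norm in zip(states, self._meas[1:], self._norms):
            diff = self.grid.pack(state.nbar) - self.grid.pack(meas)
            res.append(diff / np.sqrt(norm))
        return np.concatenate(res)

    def misfit(self, params: GrowthParams) -> float:
        """Relative-L2 data misfit J(D, rho) >= 0."""
        self._check_bounds(params)
        return float(np.sum(self.residuals(params) ** 2))

    def _check_bounds(self, params: GrowthParams) -> None:
        (dlo, dhi), (rlo, rhi) = self.bounds
        if not (dlo <= params.d <= dhi and rlo <= params.rho <= rhi):
            raise ValueError(
                f"params (D={params.d}, rho={params.rho}) outside the "
                f"admissible box {self.bounds}")

    # -- Gauss-Newton fit --------------------------------------------------

    def fit(self, init: GrowthParams | None = None,
            max_iter: int = MAX_ITER) -> "TumorGrowthResults":
        """Bound-constrained Gauss-Newton fit of (D, rho).

        Returns the best accepted iterate; ``converged`` is False (not an
        exception) when the iteration budget is exhausted before the
        relative objective change drops below ``1e-6``.
        """
        if init is None:
            init = GrowthParams(INIT_D, INIT_RHO, nbar_th=self.nbar_th)
        self._check_bounds(init)
        lo = np.log(np.array([self.bounds[0][0], self.bounds[1][0]]))
        hi = np.log(np.array([self.bounds[0][1], self.bounds[1][1]]))

        def unpack(u):
            d, rho = np.exp(u)
            return GrowthParams(float(d), float(rho), nbar_th=self.nbar_th)

        u = np.clip(np.log([init.d, init.rho]), lo, hi)
        r = self.residuals(unpack(u))
        obj = float(r @ r)
        trajectory = [(unpack(u), obj)]
        converged = False
        n_iter = 0
        jac = None

        for n_iter in range(1, max_iter + 1):
            # forward-difference Jacobian in log-parameters
            jac = np.empty((len(r), 2))
            for k in range(2):
                u_k = u.copy()
                u_k[k] = min(u_k[k] + FD_STEP, hi[k])
                h = u_k[k] - u[k]
                if h == 0:  # at the upper bound: difference backwards
                    u_k[k] = u[k] - FD_STEP
                    h = -FD_STEP
                try:
                    r_k = self.residuals(unpack(u_k))
                except SolverError:  # probe failed: difference the other way
                    u_k[k] = u[k] - h
                    h = -h
                    r_k = self.residuals(unpack(u_k))
                jac[:, k] = (r_k - r) / h
            g = jac.T @ r
            H = jac.T @ jac + 1e-12 * np.eye(2)
            delta = np.linalg.solve(H, -g)

            # projected step-halving line search
            accepted = False
            for _ in range(MAX_HALVINGS + 1):
                u_new = np.clip(u + delta, lo, hi)
                try:
                    r_new = self.residuals(unpack(u_new))
                    obj_new = float(r_new @ r_new)
                except SolverError:  # infeasible trial point: shorten step
                    obj_new = np.inf
                if obj_new < obj:
                    accepted = True
                    break
                delta = 0.5 * delta
            if not accepted:
                converged = True  # no descent direction left: stationary
                break
            rel_change = (obj - obj_new) / max(obj, 1e-300)
            u, r, obj = u_new, r_new, obj_new
            trajectory.append((unpack(u), obj))
            if rel_change < OBJ_RTOL:
                converged = True
                break

        params = unpack(u)
        se = self._standard_errors(jac, r) if jac is not None else (np.nan,) * 2
        return TumorGrowthResults(
            model=self, params=params, objective=obj, iterations=n_iter,
            converged=converged, trajectory=trajectory,
            log_param_se=se,
        )

    @staticmethod
    def _standard_errors(jac, r):
        """Asymptotic Gauss-Newton standard errors of (log D, log rho)."""
        dof = max(len(r) - 2, 1)
        sigma2 = float(r @ r) / dof
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            return tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
        except np.linalg.LinAlgError:
            return (float("nan"), float("nan"))


@dataclass
class TumorGrowthResults:
    """Calibration result: estimates, misfit, trace and diagnostics."""

    model: TumorGrowthModel
    params: GrowthParams
    objective: float
    iterations: int
    converged: bool
    trajectory: list = field(default_factory=list)
    log_param_se: tuple = (float("nan"), float("nan"))

    def simulate(self, output_times) -> list[DensityState]:
        """Forward simulation at the fitted parameters (e.g. a forecast)."""
        return self.model.simulate(self.params, output_times)

    def summary(self) -> str:
        p, se = self.params, self.log_param_se
        lines = [
            "Fisher-Kolmogorov growth model — Gauss-Newton calibration",
            "=" * 60,
            f"scans fitted:        {self.model.series.n_scans - 1} "
            f"(of {self.model.series.n_scans}; scan 1 = initial condition)",
            f"prostate volume:     {self.model.grid.prostate_volume_cc():.2f} cc",
            f"D   (mm^2/day):      {p.d:.4e}   (se log D:   {se[0]:.3g})",
            f"rho (1/day):         {p.rho:.4e}   (se log rho: {se[1]:.3g})",
            f"relative-L2 misfit:  {self.objective:.6e}",
            f"iterations:          {self.iterations}   "
            f"converged: {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "d": self.params.d,
            "rho": self.params.rho,
            "objective": self.objective,
            "iterations": self.iterations,
            "converged": self.converged,
            "log_param_se": list(map(float, self.log_param_se)),
            "trajectory": [
                {"d": p.d, "rho": p.rho, "objective": o}
                for p, o in self.trajectory
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def plot_fit(self, ax=None):
        """Misfit trace across Gauss-Newton iterations."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy([o for _, o in self.trajectory], marker="o")
        ax.set_xlabel("accepted iteration")
        ax.set_ylabel("relative-L2 misfit")
        return ax


def grid_search(model: TumorGrowthModel, n: int = 20) -> tuple[GrowthParams, float]:
    """Brute-force misfit minimum on an n x n log-spaced (D, rho) grid over
    the admissible box; the independent oracle for the Gauss-Newton fit."""
    (dlo, dhi), (rlo, rhi) = model.bounds
    ds = np.logspace(np.log10(dlo), np.log10(dhi), n)
    rs = np.logspace(np.log10(rlo), np.log10(rhi), n)
    best, best_obj = None, np.inf
    for d in ds:
        for rho in rs:
            try:
                obj = model.misfit(GrowthParams(float(d), float(rho),
                                                nbar_th=model.nbar_th))
            except SolverError:  # no admissible discrete solution there
                continue
            if obj < best_obj:
                best, best_obj = GrowthParams(float(d), float(rho)), obj
    return best, best_obj
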