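"""Stiff integration of the model and steady-state location."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import model
from .params import ExternalPools, KineticParameters

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "find_steady_state",
    "DEFAULT_T_END",
    "DEFAULT_REPORT_STEP",
]

DEFAULT_T_END = 2.0e5      # s
DEFAULT_REPORT_STEP = 30.0  # s, reporting increment of the reference solver
STEADY_DERIV_TOL = 1e-10   # mM/s, max |dx/dt| for a declared steady state


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid partial trajectory."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class Trajectory:
    """Time course on a uniform reporting grid.

    ``states`` has one column per channel; model trajectories use the nine
    metabolite names, but any channel naming is accepted (the regime
    classifier is agnostic to the source of the signal).
    """

    times: np.ndarray                      # (n,) seconds, strictly increasing
    states: np.ndarray                     # (n, m) mM
    names: tuple[str, ...] = model.METABOLITES
    params_digest: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states")
        self.names = tuple(self.names)
        if len(self.names) != self.states.shape[1]:
            raise ValueError("names/state-columns mismatch")

    @property
    def report_step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def channel(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    # -- I/O ------------------------------------------------------------
    def to_frame(self, tidy: bool = False) -> pd.DataFrame:
        wide = pd.DataFrame(self.states, columns=list(self.names))
        wide.insert(0, "time", self.times)
        if not tidy:
            return wide
        return wide.melt(id_vars="time", var_name="metabolite",
                         value_name="concentration")

    def write_csv(self, path: str | Path, tidy: bool = False) -> None:
        self.to_frame(tidy=tidy).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        if {"time", "metabolite", "concentration"} <= set(df.columns):
            df = df.pivot(index="time", columns="metabolite",
                          values="concentration").reset_index()
        names = tuple(c for c in df.columns if c != "time")
        return cls(times=df["time"].to_numpy(),
                   states=df[list(names)].to_numpy(), names=names)


def _solve(p, ext, x0, t0, t1, step, rtol, atol, method, dense=False):
    t_eval = np.arange(t0, t1 + 0.5 * step, step)
    t_eval = t_eval[t_eval <= t1]
    sol = solve_ivp(model.rhs, (t0, t1), x0, args=(p, ext), method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    return sol


def integrate(p: KineticParameters,
              ext: ExternalPools | None = None,
              x0: Sequence[float] | None = None,
              t_end: float = DEFAULT_T_END,
              report_step: float = DEFAULT_REPORT_STEP,
              rtol: float = 1e-8,
              atol: float = 1e-12,
              method: str = "LSODA") -> Trajectory:
    """Integrate the model from ``x0`` (default: the empty-pathway state).

    Uses a stiff-capable solver (LSODA by default, automatic stiffness
    switching) with adaptive internal steps and a uniform reporting grid.
    Raises :exc:`IntegrationError` on solver failure, attaching the partial
    trajectory computed so far.
    """
    if ext is None:
        ext = ExternalPools()
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = np.zeros(model.N_STATES) if x0 is None else np.asarray(x0, float)
    if x0.shape != (model.N_STATES,) or not np.all(np.isfinite(x0)) or np.any(x0 < 0):
        raise ValueError("x0 must be 9 finite non-negative concentrations")
    sol = _solve(p, ext, x0, 0.0, t_end, report_step, rtol, atol, method)
    meta = {"rtol": rtol, "atol": atol, "method": method, "t_end": t_end,
            "atp": ext.atp, "imp": ext.imp}
    if not sol.success:
        partial = None
        if sol.t.size:
            partial = Trajectory(sol.t, sol.y.T, params_digest=p.digest(),
                                 meta=meta)
        raise IntegrationError(f"solver failed: {sol.message}", partial)
    return Trajectory(sol.t, np.clip(sol.y.T, 0.0, None),
                      params_digest=p.digest(), meta=meta)


def _refine_fixed_point(p, ext, x_guess, tol=STEADY_DERIV_TOL):
    """Newton-refine a candidate fixed point; None if it fails the criterion."""
    fun = lambda x: model.rhs(0.0, x, p, ext)
    x_guess = np.clip(x_guess, 0.0, None)
    if np.max(np.abs(fun(x_guess))) < tol:
        return x_guess
    try:
        res = root(fun, x_guess, method="hybr",
                   options={"xtol": 1e-13})
    except Exception:
        return None
    x = res.x
    if not res.success or np.any(x < -1e-12) or not np.all(np.isfinite(x)):
        return None
    x = np.clip(x, 0.0, None)
    if np.max(np.abs(fun(x))) >= tol:
        return None
    return x


def jacobian(p: KineticParameters, ext: ExternalPools, x,
             eps: float = 1e-7) -> np.ndarray:
    """Finite-difference Jacobian of the right-hand side at ``x``."""
    x = np.asarray(x, float)
    f0 = model.rhs(0.0, x, p, ext)
    J = np.empty((model.N_STATES, model.N_STATES))
    for j in range(model.N_STATES):
        h = eps * max(abs(x[j]), 1e-6)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (model.rhs(0.0, xp, p, ext) - f0) / h
    return J


def is_stable(p: KineticParameters, ext: ExternalPools, x,
              margin: float = 0.0) -> bool:
    """True if all Jacobian eigenvalues at ``x`` have real part < -margin."""
    eig = np.linalg.eigvals(jacobian(p, ext, x))
    return bool(np.all(eig.real < -margin))


def find_steady_state(p: KineticParameters,
                      ext: ExternalPools | None = None,
                      x0: Sequence[float] | None = None,
                      t_max: float = DEFAULT_T_END,
                      deriv_tol: float = STEADY_DERIV_TOL,
                      require_stable: bool = True,
                      rtol: float = 1e-8,
                      atol: float = 1e-12,
                      n_chunks: int = 8) -> np.ndarray | None:
    """Locate the attracting fixed point reached from ``x0``, or ``None``.

    Integrates in chunks with early exit once the derivative criterion
    ``max|dx/dt| < deriv_tol`` is close (within 1e4×), then Newton-refines the
    endpoint. Returns ``None`` when the trajectory does not converge (e.g. a
    limit cycle), when root refinement diverges, or when the refined point is
    linearly unstable (``require_stable``).
    """
    if ext is None:
        ext = ExternalPools()
    x = np.zeros(model.N_STATES) if x0 is None else np.asarray(x0, float)
    chunk = t_max / n_chunks
    converging = False
    for _ in range(n_chunks):
        sol = solve_ivp(model.rhs, (0.0, chunk), x, args=(p, ext),
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            return None
        x = np.clip(sol.y[:, -1], 0.0, None)
        d = np.max(np.abs(model.rhs(0.0, x, p, ext)))
        if d < deriv_tol * 1e4:
            converging = True
            break
    if not converging:
        # final check at the full horizon
        if np.max(np.abs(model.rhs(0.0, x, p, ext))) >= deriv_tol * 1e4:
            return None
    xs = _refine_fixed_point(p, ext, x, tol=deriv_tol)
    if xs is None:
        return None
    # guard against refining onto an unstable fixed point inside a limit cycle
    if require_stable and not is_stable(p, ext, xs):
        return None
    return xs
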