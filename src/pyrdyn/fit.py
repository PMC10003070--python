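"""Estimation of generalized rate constants from steady-state metabolite data.

The fitting target is a set of per-dataset steady-state concentration tables
(e.g. two chemostat strains measured at the same dilution rate but with
systematically different absolute scales). The objective is a sum of squared
log-residuals between model steady states and observations, with one
multiplicative normalization coefficient per dataset reconciling the scale
differences: dataset 0 is the reference (coefficient fixed at 1), the other
coefficients are profiled out in closed form (geometric-mean matching in log
space). Optimization is a seeded population-based global search
(differential evolution in log-parameter space) with optional local polish.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .params import ExternalPools, KineticParameters, default_parameters
from .simulate import _refine_fixed_point, find_steady_state, is_stable
from . import model

__all__ = [
    "SteadyStateDataset",
    "FitResult",
    "predict_steady_state",
    "objective",
    "fit_parameters",
    "read_datasets_csv",
    "write_datasets_csv",
    "compare_datasets",
]

log = logging.getLogger(__name__)

OBSERVABLE_METABOLITES = ("casp", "dho", "ump", "udp", "utp", "ctp")

#: log-Hill parameters behave badly below 1; bounds are user-supplied anyway
_FIT_T_MAX = 1.0e5


@dataclass(frozen=True)
class SteadyStateDataset:
    """One steady-state metabolite table with its external pools."""

    dataset_id: str
    concentrations: dict[str, float]      # metabolite -> mM, subset of model
    pools: ExternalPools

    def __post_init__(self) -> None:
        for m, c in self.concentrations.items():
            if m not in model.METABOLITES:
                raise ValueError(f"unknown metabolite {m!r}")
            if not (np.isfinite(c) and c > 0):
                raise ValueError(f"{self.dataset_id}/{m}: concentration must be > 0")


@dataclass
class FitResult:
    """Outcome of a parameter fit."""

    params: KineticParameters
    norms: dict[str, float]               # dataset_id -> normalization coeff
    objective: float
    free_params: tuple[str, ...]
    seed: int | None
    trace: list[float] = field(default_factory=list)   # best objective per gen
    nfev: int = 0
    success: bool = True
    message: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "objective": float(self.objective),
            "free_params": list(self.free_params),
            "fitted": {k: float(self.params[k]) for k in self.free_params},
            "norms": {k: float(v) for k, v in self.norms.items()},
            "seed": self.seed,
            "nfev": self.nfev,
            "success": bool(self.success),
            "message": self.message,
            "trace": [float(v) for v in self.trace],
            "params_digest": self.params.digest(),
            "all_params": self.params.to_dict(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def predict_steady_state(p: KineticParameters, ds: SteadyStateDataset,
                         x0=None) -> dict[str, float] | None:
    """Model steady state under the dataset's external pools, or None.

    With ``x0`` given, a fast path Newton-refines the fixed point from that
    guess and accepts it if it is linearly stable; otherwise (or on failure)
    the trajectory-based finder is used. The fast path makes the optimizer
    loop tractable; it assumes the attracting state near the guess is the one
    reached from the empty pathway, which holds in the steady regime.
    """
    xs = None
    if x0 is not None:
        cand = _refine_fixed_point(p, ds.pools, np.asarray(x0, float))
        if cand is not None and is_stable(p, ds.pools, cand):
            xs = cand
    if xs is None:
        xs = find_steady_state(p, ds.pools, t_max=_FIT_T_MAX)
    if xs is None:
        return None
    return dict(zip(model.METABOLITES, xs))


def _log_residuals(pred: dict[str, float], ds: SteadyStateDataset,
                   floor: float = 1e-12) -> np.ndarray:
    obs = ds.concentrations
    return np.array([np.log(max(pred[m], floor)) - np.log(obs[m])
                     for m in sorted(obs)])


def objective(p: KineticParameters,
              datasets: Sequence[SteadyStateDataset],
              norms: dict[str, float] | None = None,
              return_norms: bool = False,
              x0_hints: dict[str, np.ndarray] | None = None):
    """Sum of squared log-residuals between model and observations (>= 0).

    Model predictions for dataset k are multiplied by its normalization
    coefficient. If ``norms`` is None the coefficients are profiled: the
    first dataset (in the given order) is the reference with coefficient 1,
    each further coefficient is the value that zeroes the mean log-residual
    of its dataset. Returns infinity when any dataset has no steady state.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    total = 0.0
    fitted_norms: dict[str, float] = {}
    for k, ds in enumerate(datasets):
        hint = x0_hints.get(ds.dataset_id) if x0_hints else None
        pred = predict_steady_state(p, ds, x0=hint)
        if pred is None or any(pred[m] <= 0 for m in ds.concentrations):
            if return_norms:
                return np.inf, {}
            return np.inf
        res = _log_residuals(pred, ds)
        if norms is not None:
            c = norms.get(ds.dataset_id, 1.0)
        elif k == 0:
            c = 1.0
        else:
            c = float(np.exp(-np.mean(res)))   # closed-form profile
        fitted_norms[ds.dataset_id] = c
        total += float(np.sum((res + np.log(c)) ** 2))
    if return_norms:
        return total, fitted_norms
    return total


def fit_parameters(datasets: Sequence[SteadyStateDataset],
                   free_params: Sequence[str],
                   bounds: dict[str, tuple[float, float]] | None = None,
                   seed: int | None = 0,
                   base: KineticParameters | None = None,
                   maxiter: int = 60,
                   popsize: int = 12,
                   tol: float = 1e-8,
                   polish: bool = True,
                   workers: int = 1) -> FitResult:
    """Fit the named parameters to the datasets by global optimization.

    The search runs in log10-parameter space (concentration-like constants
    span orders of magnitude) with a seeded differential-evolution optimizer;
    the remaining parameters are held at ``base`` (default: the shipped
    defaults). With empty ``free_params`` the objective is evaluated once at
    ``base`` and returned.
    """
    base = default_parameters() if base is None else base
    free = tuple(free_params)
    for name in free:
        if name not in base.names():
            raise KeyError(f"unknown parameter {name!r}")
    if not free:
        obj, norms = objective(base, datasets, return_norms=True)
        return FitResult(params=base, norms=norms, objective=float(obj),
                         free_params=free, seed=seed, nfev=1,
                         success=bool(np.isfinite(obj)),
                         message="no free parameters")
    if bounds is None or any(n not in bounds for n in free):
        missing = [n for n in free if not bounds or n not in bounds]
        raise ValueError(f"bounds required for free parameters: {missing}")
    lb = np.log10([bounds[n][0] for n in free])
    ub = np.log10([bounds[n][1] for n in free])
    if not np.all(np.isfinite(lb)) or not np.all(ub > lb):
        raise ValueError("bounds must be positive with hi > lo")

    # per-dataset fixed-point hints for the objective's fast path
    hints: dict[str, np.ndarray] = {}
    for ds in datasets:
        xs = find_steady_state(base, ds.pools, t_max=_FIT_T_MAX)
        if xs is not None:
            hints[ds.dataset_id] = xs

    nfev = 0
    trace: list[float] = []

    def _params_at(z: np.ndarray) -> KineticParameters:
        vals = 10.0 ** np.asarray(z)
        # Hill exponents are bounded below by 1 in the model
        return base.replace(**{n: (max(v, 1.0) if n.startswith("h_") else v)
                               for n, v in zip(free, vals)})

    def fun(z: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        try:
            p = _params_at(z)
        except ValueError:
            return np.inf
        return objective(p, datasets, x0_hints=hints)

    def cb(xk, convergence=0.0):
        trace.append(fun(xk))

    result = differential_evolution(
        fun, bounds=list(zip(lb, ub)), seed=seed, maxiter=maxiter,
        popsize=popsize, tol=tol, polish=polish, init="sobol",
        updating="immediate", workers=workers, callback=cb)
    p_best = _params_at(result.x)
    obj, norms = objective(p_best, datasets, return_norms=True,
                           x0_hints=hints)
    ok = bool(np.isfinite(obj))
    return FitResult(params=p_best, norms=norms, objective=float(obj),
                     free_params=free, seed=seed, trace=trace, nfev=nfev,
                     success=ok,
                     message=result.message if ok else
                     "budget exhausted without finite objective")


# -- dataset CSV dialect -----------------------------------------------------

def write_datasets_csv(datasets: Sequence[SteadyStateDataset],
                       path: str | Path) -> None:
    """Long CSV: dataset_id, metabolite, concentration_mM, kind.

    External pools are stored as rows of kind ``pool`` (metabolites atp/imp);
    observed metabolites have kind ``observed``.
    """
    rows = []
    for ds in datasets:
        for m, c in ds.concentrations.items():
            rows.append((ds.dataset_id, m, c, "observed"))
        rows.append((ds.dataset_id, "atp", ds.pools.atp, "pool"))
        rows.append((ds.dataset_id, "imp", ds.pools.imp, "pool"))
    pd.DataFrame(rows, columns=["dataset_id", "metabolite",
                                "concentration_mM", "kind"]
                 ).to_csv(path, index=False)


def read_datasets_csv(path: str | Path) -> list[SteadyStateDataset]:
    df = pd.read_csv(path)
    need = {"dataset_id", "metabolite", "concentration_mM"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    if "kind" not in df.columns:
        df["kind"] = np.where(df["metabolite"].isin(("atp", "imp")),
                              "pool", "observed")
    out = []
    for did, g in df.groupby("dataset_id", sort=False):
        pools = dict(zip(g.loc[g["kind"] == "pool", "metabolite"],
                         g.loc[g["kind"] == "pool", "concentration_mM"]))
        conc = dict(zip(g.loc[g["kind"] == "observed", "metabolite"],
                        g.loc[g["kind"] == "observed", "concentration_mM"]))
        out.append(SteadyStateDataset(
            dataset_id=str(did), concentrations=conc,
            pools=ExternalPools(atp=float(pools.get("atp", 9.6)),
                                imp=float(pools.get("imp", 0.27)))))
    return out


def compare_datasets(a: SteadyStateDataset, b: SteadyStateDataset):
    """Convenience diagnostic: two-sample t test on log concentrations.

    A plain location test on the shared metabolites' log concentrations,
    useful to confirm that two tables differ systematically in scale before
    fitting with normalization coefficients. Returns (t, p_value).
    """
    from scipy import stats
    shared = sorted(set(a.concentrations) & set(b.concentrations))
    if len(shared) < 2:
        raise ValueError("need at least two shared metabolites")
    la = np.log([a.concentrations[m] for m in shared])
    lb = np.log([b.concentrations[m] for m in shared])
    t, pv = stats.ttest_rel(la, lb)
    return float(t), float(pv)
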