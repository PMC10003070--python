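"""Synthetic fixtures: pseudo-experimental steady-state tables, labelled
trajectory suites for validating the oscillation classifier, an
oscillation-capable parameter set, and a Hopf normal-form benchmark.

The steady-state generator emulates the situation of two chemostat datasets
measured at the same dilution rate (0.1 1/h) in two strains with different
external ATP/IMP pools and a systematic between-dataset scale difference,
which the fitting module reconciles with normalization coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import model
from .fit import OBSERVABLE_METABOLITES, SteadyStateDataset
from .params import ExternalPools, KineticParameters, default_parameters
from .simulate import Trajectory, find_steady_state

__all__ = [
    "make_steady_datasets",
    "make_labelled_trajectories",
    "make_oscillatory_base",
    "LabelledTrajectory",
    "hopf_normal_form_trajectory",
    "DEFAULT_POOLS",
    "DEFAULT_SCALE_FACTORS",
]

#: chemostat external pools (ATP, IMP) mM for the two emulated strains
DEFAULT_POOLS = (ExternalPools(atp=0.33, imp=0.098),   # BW25113-like
                 ExternalPools(atp=9.6, imp=0.27))     # NCM3722-like
DEFAULT_DATASET_IDS = ("synthetic-BW25113", "synthetic-NCM3722")
#: systematic between-dataset measurement scale (dataset 0 is the reference)
DEFAULT_SCALE_FACTORS = (1.0, 2.0)
DEFAULT_NOISE_CV = 0.10


def make_steady_datasets(p_true: KineticParameters | None = None,
                         n_datasets: int = 2,
                         scale_factors=DEFAULT_SCALE_FACTORS,
                         noise_cv: float = DEFAULT_NOISE_CV,
                         seed: int = 0,
                         pools=DEFAULT_POOLS,
                         metabolites=OBSERVABLE_METABOLITES,
                         ) -> list[SteadyStateDataset]:
    """Generate steady-state tables from a ground-truth parameter set.

    Dataset k is the model steady state under its external pools, multiplied
    by ``scale_factors[k]`` and by median-unbiased lognormal noise with
    coefficient of variation ``noise_cv``. Seed-deterministic.
    """
    p_true = default_parameters() if p_true is None else p_true
    if not (len(scale_factors) >= n_datasets and len(pools) >= n_datasets):
        raise ValueError("need a scale factor and pools per dataset")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    out = []
    for k in range(n_datasets):
        xs = find_steady_state(p_true, pools[k])
        if xs is None:
            raise RuntimeError(
                f"ground-truth parameters have no steady state for pools {k}")
        ss = dict(zip(model.METABOLITES, xs))
        conc = {}
        for m in metabolites:
            noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            conc[m] = ss[m] * scale_factors[k] * noise
        did = (DEFAULT_DATASET_IDS[k] if k < len(DEFAULT_DATASET_IDS)
               else f"synthetic-{k}")
        out.append(SteadyStateDataset(dataset_id=did, concentrations=conc,
                                      pools=pools[k]))
    return out


@dataclass(frozen=True)
class LabelledTrajectory:
    """A classifier fixture with its ground truth."""

    trajectory: Trajectory
    label: str                    # steady | oscillatory
    period: float | None = None   # seconds, for oscillatory members
    kind: str = ""                # sine | damped | constant | relaxation


def _relaxation_wave(phase: np.ndarray, skew: float = 0.8) -> np.ndarray:
    """Fast-rise slow-fall periodic wave (square-ish), zero-mean, unit amp."""
    frac = (phase / (2 * np.pi)) % 1.0
    y = np.where(frac < skew, frac / skew, (1.0 - frac) / (1.0 - skew))
    return 2.0 * y - 1.0


def make_labelled_trajectories(n: int, seed: int = 0,
                               t_end: float | None = None,
                               report_step: float = 30.0,
                               noise_max: float = 0.10
                               ) -> list[LabelledTrajectory]:
    """A labelled suite of single-channel signals for classifier validation.

    Cycles through four families: sustained sinusoids (period 200-5000 s,
    additive noise up to ``noise_max`` of the amplitude), damped sinusoids
    (>= 15% amplitude loss per period: transients, hence steady), constants
    with additive noise (steady), and sustained relaxation waves
    (oscillatory). Records are long enough to hold at least ten periods
    (``t_end=None``, the default; pass a value to fix the horizon instead).
    Seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    out: list[LabelledTrajectory] = []
    kinds = ("sine", "damped", "constant", "relaxation")
    for i in range(n):
        kind = kinds[i % len(kinds)]
        level = 10.0 ** rng.uniform(-1.5, 1.0)
        period = float(rng.uniform(200.0, 5000.0))
        # record long enough to hold >= 10 periods (half is burn-in)
        t_i = t_end if t_end is not None else max(2.0e4, 10.0 * period)
        t = np.arange(0.0, t_i + report_step / 2, report_step)
        eps = rng.normal(0.0, 1.0, len(t))
        amp = level * rng.uniform(0.2, 0.8)
        phase = rng.uniform(0.0, 2 * np.pi)
        noise_frac = rng.uniform(0.0, noise_max)
        w = 2 * np.pi / period
        if kind == "sine":
            y = level + amp * np.sin(w * t + phase) + noise_frac * amp * eps
            label, per = "oscillatory", period
        elif kind == "damped":
            decay = rng.uniform(0.15, 0.5)              # amplitude loss/period
            lam = -np.log(1.0 - decay) / period
            y = level + amp * np.exp(-lam * t) * np.sin(w * t + phase)
            y = y + noise_frac * 0.02 * amp * eps
            label, per = "steady", None
        elif kind == "constant":
            y = level * (1.0 + noise_frac * eps)
            label, per = "steady", None
        else:                                           # relaxation
            y = level + amp * _relaxation_wave(w * t + phase)
            y = y + noise_frac * amp * eps
            label, per = "oscillatory", period
        traj = Trajectory(times=t, states=np.abs(y)[:, None],
                          names=("signal",), meta={"kind": kind})
        out.append(LabelledTrajectory(trajectory=traj, label=label,
                                      period=per, kind=kind))
    return out


def make_oscillatory_base() -> KineticParameters:
    """The oscillation-capable parameter set of the reduced model.

    Joins the published oscillation-regime rate constants (k2 = 0.0031,
    k3 = 0.00351, k9 = 1.74e-4 mM/s, h_UMP1 = 2.1, with fully noncompetitive
    UMP-kinase inhibition, r = 1) with the shipped default affinity
    constants; the defaults were calibrated once so that this set yields a
    sustained limit cycle while the default (steady-regime) set does not
    (see docs/methods.md). Deterministic: no randomness.
    """
    return default_parameters(k2=0.0031, k3=0.00351, k9=1.74e-4,
                              h_UMP1=2.1, r=1.0)


def hopf_normal_form_trajectory(mu: float,
                                omega: float = 2 * np.pi / 600.0,
                                x0: tuple[float, float] = (1.0, 0.0),
                                t_end: float = 2.0e4,
                                report_step: float = 30.0) -> Trajectory:
    """Integrate the supercritical Hopf normal form; critical point mu = 0.

        dx/dt = mu*x - omega*y - x*(x^2+y^2)
        dy/dt = omega*x + mu*y - y*(x^2+y^2)

    For mu < 0 the origin is a stable spiral (steady); for mu > 0 a stable
    limit cycle of radius sqrt(mu) and period 2*pi/omega. Used as the
    closed-form benchmark for regime-boundary bisection.
    """
    def f(t, z):
        x, y = z
        r2 = x * x + y * y
        return [mu * x - omega * y - x * r2, omega * x + mu * y - y * r2]

    t_eval = np.arange(0.0, t_end + report_step / 2, report_step)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(f, (0.0, t_end), list(x0), t_eval=t_eval,
                    rtol=1e-9, atol=1e-12, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"normal-form integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, names=("x", "y"),
                      meta={"mu": mu, "omega": omega})
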