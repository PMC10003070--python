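"""Regime mapping over the Hill x r parameter space, boundary location and
parameter-sensitivity ranking.

The regime map emulates a three-dimensional scan of the Hill exponents of the
three nucleotide feedbacks on carbamoyl-phosphate synthetase (h_UMP1, h_UDP1,
h_UTP1, each in [1, 10]) crossed with the UMP-kinase inhibition-mechanism
parameter r in [0, 1]: every grid point is simulated and classified.
Regime boundaries along a single parameter are located by bisection on the
classification outcome, and sensitivities are normalized finite-difference
log-derivatives of the steady state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import model
from .params import ExternalPools, KineticParameters
from .regime import RegimeCall, classify
from .simulate import (DEFAULT_REPORT_STEP, DEFAULT_T_END, IntegrationError,
                       find_steady_state, integrate)

__all__ = [
    "RegimeMap",
    "scan_hill_space",
    "classify_parameters",
    "bisect_label_boundary",
    "boundary_bisect",
    "sensitivity_rank",
]

log = logging.getLogger(__name__)

HILL_AXES = ("h_UMP1", "h_UDP1", "h_UTP1")
DEFAULT_R_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 10))


@dataclass
class RegimeMap:
    """Regime label per (h_UMP1, h_UDP1, h_UTP1, r) grid point."""

    table: pd.DataFrame            # columns: axes..., label, period, evidence
    axes: tuple[str, ...]
    grids: dict[str, tuple[float, ...]]
    base_digest: str
    meta: dict = field(default_factory=dict)

    def counts(self, **where: float) -> dict[str, int]:
        """Label counts, optionally restricted (e.g. ``counts(r=1.0)``)."""
        t = self.table
        for k, v in where.items():
            t = t[np.isclose(t[k], v)]
        c = t["label"].value_counts().to_dict()
        return {lab: int(c.get(lab, 0)) for lab in
                ("steady", "oscillatory", "undetermined")}

    def write(self, csv_path: str | Path,
              meta_path: str | Path | None = None) -> None:
        self.table.to_csv(csv_path, index=False)
        if meta_path is not None:
            doc = {"axes": list(self.axes),
                   "grids": {k: list(v) for k, v in self.grids.items()},
                   "base_digest": self.base_digest, **self.meta}
            Path(meta_path).write_text(json.dumps(doc, indent=2))


def classify_parameters(p: KineticParameters,
                        ext: ExternalPools | None = None,
                        t_end: float = DEFAULT_T_END,
                        report_step: float = DEFAULT_REPORT_STEP,
                        rtol: float = 1e-8,
                        atol: float = 1e-12) -> RegimeCall:
    """Simulate one parameter set from the empty state and classify it.

    Fast path: if the trajectory settles onto a stable fixed point (checked
    with the steady-state finder at a shortened horizon first), the point is
    steady without spectral analysis; otherwise the full record is classified.
    """
    if ext is None:
        ext = ExternalPools()
    ss = find_steady_state(p, ext, t_max=t_end, rtol=rtol, atol=atol)
    if ss is not None:
        return RegimeCall("steady",
                          amplitude={m: 0.0 for m in model.METABOLITES})
    try:
        traj = integrate(p, ext, t_end=t_end, report_step=report_step,
                         rtol=rtol, atol=atol)
    except IntegrationError as err:
        log.warning("solver failure during scan: %s", err)
        return RegimeCall("undetermined", diagnostic=str(err))
    return classify(traj)


def scan_hill_space(base: KineticParameters,
                    ext: ExternalPools | None = None,
                    hill_step: int = 1,
                    r_values: Sequence[float] = DEFAULT_R_GRID,
                    hill_range: tuple[float, float] = (1.0, 10.0),
                    t_end: float = DEFAULT_T_END,
                    rtol: float = 1e-8,
                    atol: float = 1e-12,
                    progress: bool = False) -> RegimeMap:
    """Map regimes over the (h_UMP1, h_UDP1, h_UTP1) x r grid.

    Each Hill exponent runs over ``hill_range`` in increments of
    ``hill_step``; every grid point replaces those four parameters in
    ``base``, simulates from the empty state and classifies. Deterministic
    given ``base``. Solver failures are logged and labelled undetermined.
    """
    if hill_step < 1:
        raise ValueError("hill_step must be >= 1")
    if ext is None:
        ext = ExternalPools()
    hgrid = tuple(np.arange(hill_range[0], hill_range[1] + 1e-9, hill_step))
    rgrid = tuple(float(r) for r in r_values)
    rows = []
    total = len(hgrid) ** 3 * len(rgrid)
    done = 0
    for r in rgrid:
        for h1 in hgrid:
            for h2 in hgrid:
                for h3 in hgrid:
                    p = base.replace(h_UMP1=h1, h_UDP1=h2, h_UTP1=h3, r=r)
                    call = classify_parameters(p, ext, t_end=t_end,
                                               rtol=rtol, atol=atol)
                    rows.append({"h_UMP1": h1, "h_UDP1": h2, "h_UTP1": h3,
                                 "r": r, "label": call.label,
                                 "period": call.period,
                                 "evidence": call.evidence})
                    done += 1
                    if progress and done % 16 == 0:
                        log.info("scan %d/%d", done, total)
    grids = {"h_UMP1": hgrid, "h_UDP1": hgrid, "h_UTP1": hgrid, "r": rgrid}
    return RegimeMap(table=pd.DataFrame(rows),
                     axes=HILL_AXES + ("r",), grids=grids,
                     base_digest=base.digest(),
                     meta={"t_end": t_end, "hill_step": hill_step})


def bisect_label_boundary(label_at: Callable[[float], str],
                          lo: float, hi: float, tol: float,
                          max_iter: int = 200) -> tuple[float, float, float]:
    """Bisect a scalar parameter on a binary classification outcome.

    ``label_at`` must return 'steady' or 'oscillatory' at both ``lo`` and
    ``hi``, and the two labels must differ. Returns ``(lo, hi, mid)`` with
    ``hi - lo <= tol``, the bracket containing a steady<->oscillatory
    transition. Deterministic.
    """
    la, lb = label_at(lo), label_at(hi)
    for v, lab in ((lo, la), (hi, lb)):
        if lab not in ("steady", "oscillatory"):
            raise ValueError(f"label at {v} is {lab!r}, need steady/oscillatory")
    if la == lb:
        raise ValueError(f"no boundary bracketed: both endpoints are {la!r}")
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        lm = label_at(mid)
        # an undetermined midpoint is resolved toward the oscillatory side,
        # keeping the bracket valid for the two decided labels
        side = lm if lm in ("steady", "oscillatory") else "oscillatory"
        if side == la:
            lo = mid
        else:
            hi = mid
        it += 1
    return lo, hi, 0.5 * (lo + hi)


def boundary_bisect(base: KineticParameters, param_name: str,
                    lo: float, hi: float, tol: float,
                    ext: ExternalPools | None = None,
                    t_end: float = DEFAULT_T_END) -> tuple[float, float, float]:
    """Locate a steady<->oscillatory boundary along one model parameter.

    Thin wrapper over :func:`bisect_label_boundary` using
    :func:`classify_parameters` as the oracle.
    """
    def label_at(v: float) -> str:
        return classify_parameters(base.replace(**{param_name: v}), ext,
                                   t_end=t_end).label
    return bisect_label_boundary(label_at, lo, hi, tol)


def sensitivity_rank(base: KineticParameters,
                     ext: ExternalPools | None = None,
                     rel_delta: float = 0.05,
                     param_names: Sequence[str] | None = None,
                     x0: Sequence[float] | None = None
                     ) -> list[tuple[str, float]]:
    """Rank parameters by normalized steady-state sensitivity.

    For each parameter the steady state is recomputed at p*(1 +- rel_delta)
    and the sensitivity is the max-norm over metabolites of the central
    log-derivative d ln x_i / d ln p_j (dimensionless, so invariant to units
    of either). Parameters at zero use an absolute step of ``rel_delta``.
    Returns (name, sensitivity) sorted by decreasing sensitivity.
    """
    if ext is None:
        ext = ExternalPools()
    names = tuple(param_names) if param_names is not None else base.names()
    x_ref = find_steady_state(base, ext, x0=x0)
    if x_ref is None:
        raise RuntimeError("base parameter set has no attracting steady state")
    floor = 1e-12
    out = []
    for name in names:
        v = base[name]
        if v == 0.0:
            steps = (rel_delta, 0.0)
            denom = rel_delta
        else:
            hi, lo = v * (1 + rel_delta), v * (1 - rel_delta)
            # clamp into the parameter's admissible domain (one-sided at edges)
            if name == "r":
                hi = min(hi, 1.0)
            if name.startswith("h_"):
                lo = max(lo, 1.0)
            if hi <= lo:
                out.append((name, 0.0))
                continue
            steps = (hi, lo)
            denom = np.log(hi) - np.log(lo)
        try:
            xs = [find_steady_state(base.replace(**{name: s}), ext, x0=x_ref)
                  for s in steps]
        except (ValueError, KeyError):
            raise
        if any(x is None for x in xs):
            out.append((name, float("nan")))
            continue
        dlnx = np.log(np.maximum(xs[0], floor)) - np.log(np.maximum(xs[1], floor))
        out.append((name, float(np.max(np.abs(dlnx)) / denom)))
    out.sort(key=lambda kv: (-kv[1] if np.isfinite(kv[1]) else np.inf, kv[0]))
    return out
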