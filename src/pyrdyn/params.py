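"""Model parameters for the reduced pyrimidine-biosynthesis kinetic model.

The model uses *generalized* rate constants ``k1..k9`` (enzyme concentration
times catalytic constant, folded with the saturation terms of external
substrates held constant in chemostat conditions), first-order outflow
constants ``k10, k11, k22, k23`` describing consumption of UTP/CTP/UDP in
RNA/DNA synthesis, and the affinity/Hill constants of the eight negative
feedback loops.

Every parameter carries a provenance flag:

``literature``
    the value is a published constant of the reduced model (the generalized
    rate constants and the external ATP/IMP pools),
``default``
    the value is a package default at physiological mM scales, calibrated
    once so the model reproduces the published regime dichotomy (see
    docs/methods.md).

Units are mM and seconds throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace as _dc_replace
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ExternalPools",
    "KineticParameters",
    "PARAMETER_TABLE",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "POOLS_BW25113",
    "POOLS_NCM3722",
]


@dataclass(frozen=True)
class ExternalPools:
    """External metabolite pools held constant during integration (mM)."""

    atp: float = 9.6
    imp: float = 0.27

    def __post_init__(self) -> None:
        if not (self.atp >= 0 and self.imp >= 0):
            raise ValueError("external pools must be non-negative")


#: Chemostat pools measured at dilution rate 0.1 1/h for the two strains.
POOLS_BW25113 = ExternalPools(atp=0.33, imp=0.098)
POOLS_NCM3722 = ExternalPools(atp=9.6, imp=0.27)


# name -> (default value, units, provenance)
PARAMETER_TABLE: dict[str, tuple[float, str, str]] = {
    # generalized rate constants (reduced Vmax of each enzymatic step)
    "k1": (0.012, "mM/s", "literature"),
    "k2": (0.31, "mM/s", "literature"),
    "k3": (0.351, "mM/s", "literature"),
    "k4f": (1.27, "mM/s", "literature"),
    "k4r": (0.225, "mM/s", "literature"),
    "k4": (12.28, "1", "literature"),
    "k5": (3.9, "mM/s", "literature"),
    "k5prpp": (7.5, "1", "literature"),
    "k6": (0.73, "mM/s", "literature"),
    "k7": (0.393, "mM/s", "literature"),
    "k8": (0.11, "mM/s", "literature"),
    "k9": (1.74e-5, "mM/s", "literature"),
    # outflow constants: consumption of UDP/UTP/CTP in nucleic-acid synthesis
    "k10": (2.0e-3, "1/s", "default"),
    "k11": (1.0e-3, "1/s", "default"),
    "k22": (1.0e-4, "1/s", "default"),
    "k23": (1.0e-4, "1/s", "default"),
    # V1: carbamoyl-phosphate synthetase (CPSase), loops 1/8/3 + IMP terms
    "K_UMP1": (0.05, "mM", "default"),
    "h_UMP1": (1.4, "1", "default"),
    "K_UDP1": (2.0, "mM", "default"),
    "h_UDP1": (1.0, "1", "default"),
    "K_UTP1": (0.3, "mM", "default"),
    "h_UTP1": (1.0, "1", "default"),
    "K_IMP1": (1.0, "mM", "default"),
    "Ka_IMP1": (1.0, "mM", "default"),
    "d_IMP": (1.0, "1", "default"),
    # V2: aspartate transcarbamoylase (ATCase), loops 4/5, ATP antagonism
    "Km_CAP2": (0.5, "mM", "default"),
    "h_CAP": (1.0, "1", "default"),
    "K_CTP2": (0.5, "mM", "default"),
    "K_ATP2": (2.0, "mM", "default"),
    "K_UTP2": (1.0, "mM", "default"),
    "d_CTP2": (0.1, "1", "default"),
    "d_ATP2": (2.0, "1", "default"),
    "d_UTP2": (0.3, "1", "default"),
    "w2": (1.0, "1", "default"),
    # V3: dihydroorotase
    "Km_CAASP3": (1.0, "mM", "default"),
    # V4: dihydroorotate dehydrogenase (reversible; loop 2 = orotate)
    "Km_DHO4": (0.5, "mM", "default"),
    "Km_ORO4": (0.5, "mM", "default"),
    "Ki_ORO4": (0.5, "mM", "default"),
    # V5: orotate phosphoribosyltransferase (PRPP folded into k5prpp)
    "Km_ORO5": (0.5, "mM", "default"),
    # V6: OMP decarboxylase
    "Km_OMP6": (0.2, "mM", "default"),
    # V7: UMP kinase (loop 6; r interpolates competitive<->noncompetitive)
    "Km_UMP7": (0.05, "mM", "default"),
    "K_UTP71": (0.2, "mM", "default"),
    "K_UTP72": (1.0, "mM", "default"),
    "h_UTP7": (4.0, "1", "default"),
    "r": (1.0, "1", "default"),
    # V8: nucleoside diphosphate kinase
    "Km_UDP8": (0.3, "mM", "default"),
    # V9: CTP synthetase (loop 7 = CTP product inhibition)
    "Km_UTP9": (1.0, "mM", "default"),
    "K_CTP9": (0.3, "mM", "default"),
    "h_UTP9": (2.0, "1", "default"),
}

_HILL_FIELDS = ("h_UMP1", "h_UDP1", "h_UTP1", "h_CAP", "h_UTP7", "h_UTP9")
_DELTA_FIELDS = ("d_IMP", "d_CTP2", "d_ATP2", "d_UTP2")
_AFFINITY_FIELDS = tuple(
    n for n, (_, u, _p) in PARAMETER_TABLE.items() if u == "mM"
)


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter set of the reduced model. Frozen; use :meth:`replace`."""

    k1: float
    k2: float
    k3: float
    k4f: float
    k4r: float
    k4: float
    k5: float
    k5prpp: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k22: float
    k23: float
    K_UMP1: float
    h_UMP1: float
    K_UDP1: float
    h_UDP1: float
    K_UTP1: float
    h_UTP1: float
    K_IMP1: float
    Ka_IMP1: float
    d_IMP: float
    Km_CAP2: float
    h_CAP: float
    K_CTP2: float
    K_ATP2: float
    K_UTP2: float
    d_CTP2: float
    d_ATP2: float
    d_UTP2: float
    w2: float
    Km_CAASP3: float
    Km_DHO4: float
    Km_ORO4: float
    Ki_ORO4: float
    Km_ORO5: float
    Km_OMP6: float
    Km_UMP7: float
    K_UTP71: float
    K_UTP72: float
    h_UTP7: float
    r: float
    Km_UDP8: float
    Km_UTP9: float
    K_CTP9: float
    h_UTP9: float
    #: provenance per parameter name (not part of identity/digest semantics)
    provenance: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in _AFFINITY_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"affinity constant {name} must be > 0")
        for name in _HILL_FIELDS:
            if not getattr(self, name) >= 1:
                raise ValueError(f"Hill exponent {name} must be >= 1")
        for name in _DELTA_FIELDS:
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        for name in ("k10", "k11", "k22", "k23", "k4", "k5prpp"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0")

    # -- convenience --------------------------------------------------------
    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls) if f.name != "provenance")

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given parameters replaced.

        Provenance of replaced entries is marked ``"user"``.
        """
        prov = dict(self.provenance)
        for name in changes:
            if name not in self.names():
                raise KeyError(f"unknown parameter: {name}")
            prov[name] = "user"
        return _dc_replace(self, provenance=prov, **changes)

    def __getitem__(self, name: str) -> float:
        if name not in self.names():
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterator[tuple[str, float]]:
        return ((n, getattr(self, n)) for n in self.names())

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in self.names()}

    def digest(self) -> str:
        """Stable 12-hex-digit identifier of the numeric parameter values."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_parameters(**overrides: float) -> KineticParameters:
    """The shipped default parameter set (steady-state regime).

    The generalized rate constants are the published values of the reduced
    model; affinity and Hill constants are package defaults (see module
    docstring). Keyword overrides behave like :meth:`KineticParameters.replace`.
    """
    values = {n: v for n, (v, _u, _p) in PARAMETER_TABLE.items()}
    prov = {n: p for n, (_v, _u, p) in PARAMETER_TABLE.items()}
    p = KineticParameters(provenance=prov, **values)
    return p.replace(**overrides) if overrides else p


# -- config file I/O --------------------------------------------------------

def save_parameters(p: KineticParameters, path: str | Path,
                    ext: ExternalPools | None = None) -> None:
    """Write a YAML config: one entry per symbol with value/units/provenance."""
    doc: dict = {"parameters": {}}
    for name, value in p.items():
        units = PARAMETER_TABLE[name][1]
        doc["parameters"][name] = {
            "value": float(value),
            "units": units,
            "provenance": p.provenance.get(name, "user"),
        }
    if ext is not None:
        doc["external"] = {"atp": float(ext.atp), "imp": float(ext.imp)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_parameters(path: str | Path) -> tuple[KineticParameters, ExternalPools | None]:
    """Load a YAML config written by :func:`save_parameters`.

    Entries may be bare numbers or ``{value: ..., provenance: ...}`` mappings;
    missing parameters fall back to the shipped defaults.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'parameters' key")
    base = default_parameters()
    values = base.to_dict()
    prov = dict(base.provenance)
    for name, entry in (doc.get("parameters") or {}).items():
        if name not in values:
            raise ValueError(f"{path}: unknown parameter '{name}'")
        if isinstance(entry, dict):
            if "value" not in entry:
                raise ValueError(f"{path}: parameter '{name}' has no value")
            values[name] = float(entry["value"])
            prov[name] = str(entry.get("provenance", "user"))
        else:
            values[name] = float(entry)
            prov[name] = "user"
    p = KineticParameters(provenance=prov, **values)
    ext = None
    if "external" in doc and doc["external"] is not None:
        e = doc["external"]
        ext = ExternalPools(atp=float(e.get("atp", 9.6)),
                            imp=float(e.get("imp", 0.27)))
    return p, ext
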