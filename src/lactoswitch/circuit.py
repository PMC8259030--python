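"""Kinetic model of the lambda-derived tri-stable switch circuit.

The circuit toggles an engineered *E. coli* strain between two
functionalities: accumulation of β-galactosidase (lacZ product, lactose
digestion) and expression of L-lactate dehydrogenase (ompA-lldD product,
lactate removal and pH rescue).  Six regulators are tracked at the protein
level:

* ``cI``   — repressor of pR; produced from patp2, which is weakened by a
  pH drop (modelled as repression by proton concentration).
* ``cro``  — repressor of pRM; produced from placm (lactose-activated) and
  from pRE (cII-activated positive feedback).
* ``cII``  — activator of pRE; same production as cro but degraded by the
  host protease FtsH unless cIII inhibits it.
* ``cIII`` — FtsH inhibitor; produced from pR (repressed by cI).
* ``beta_gal`` — β-galactosidase; produced from pRM (repressed by cro).
* ``l_ldh``    — L-lactate dehydrogenase; produced from pR (repressed by cI).

All promoter responses are Hill functions with a basal leak; degradation is
first order except for cII, whose rate carries an FtsH term inhibited by
cIII.  Concentrations are in arbitrary units (a.u.), time in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "RegulatorState",
    "PromoterParams",
    "CircuitParams",
    "SignalInput",
    "activity_placm",
    "activity_patp2",
    "activity_pRE",
    "hill_repression",
    "cii_degradation_rate",
    "circuit_rhs",
    "simulate_circuit",
    "find_stable_states",
    "STATE_VARS",
]

STATE_VARS = ("cI", "cro", "cII", "cIII", "beta_gal", "l_ldh")


@dataclass(frozen=True)
class RegulatorState:
    """Intracellular concentrations of the six circuit gene products (a.u.)."""

    cI: float = 0.0
    cro: float = 0.0
    cII: float = 0.0
    cIII: float = 0.0
    beta_gal: float = 0.0
    l_ldh: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "RegulatorState":
        return cls(**dict(zip(STATE_VARS, (float(v) for v in x))))


@dataclass(frozen=True)
class SignalInput:
    """Extracellular signals sensed by the circuit: lactose (mM) and pH."""

    lactose: float
    pH: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lactose) or self.lactose < 0:
            raise ValueError(f"lactose must be finite and >= 0, got {self.lactose!r}")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH must lie in (0, 14), got {self.pH!r}")


@dataclass(frozen=True)
class PromoterParams:
    """Hill-response parameters of one promoter.

    v    maximal transcription-translation rate (a.u./h)
    v0   basal leak (a.u./h), 0 <= v0 <= v
    K    half-saturation constant (mM for placm, proton mol/L for patp2,
         a.u. for the regulator-responsive promoters)
    n    Hill exponent (>= 1)
    """

    v: float
    v0: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if self.v <= 0 or self.K <= 0 or self.n < 1:
            raise ValueError("v, K must be > 0 and n >= 1")
        if self.v0 < 0 or self.v0 > self.v:
            raise ValueError("leak v0 must satisfy 0 <= v0 <= v")


@dataclass(frozen=True)
class CircuitParams:
    """Full parameter set of the circuit.

    Defaults realize the three qualitative operating regimes: β-GAL-dominant
    rest at (pH 7, no lactose), an intermediate dual-function state while
    lactose is being fermented, and an L-LDH-dominant state at low pH.
    """

    placm: PromoterParams = field(default_factory=lambda: PromoterParams(8.0, 0.05, 5.0, 2.0))
    patp2: PromoterParams = field(default_factory=lambda: PromoterParams(20.0, 0.2, 1e-6, 2.0))
    pR: PromoterParams = field(default_factory=lambda: PromoterParams(10.0, 0.05, 1.0, 2.0))
    pRM: PromoterParams = field(default_factory=lambda: PromoterParams(10.0, 0.05, 1.0, 2.0))
    pRE: PromoterParams = field(default_factory=lambda: PromoterParams(15.0, 0.1, 4.0, 2.0))
    delta_cI: float = 2.0
    delta_cro: float = 2.0
    delta_cII: float = 0.5
    delta_cIII: float = 2.0
    delta_gal: float = 0.5
    delta_ldh: float = 0.5
    delta_ftsh: float = 5.0  # maximal FtsH-mediated cII degradation (1/h)
    K_cIII: float = 1.0      # cIII concentration halving FtsH activity (a.u.)
    m_cIII: float = 2.0

    def __post_init__(self) -> None:
        for name in ("delta_cI", "delta_cro", "delta_cII", "delta_cIII",
                     "delta_gal", "delta_ldh", "delta_ftsh", "K_cIII", "m_cIII"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_promoter(self, name: str, **kw) -> "CircuitParams":
        return replace(self, **{name: replace(getattr(self, name), **kw)})


def _hill_activation(x: float, p: PromoterParams) -> float:
    xn = x ** p.n
    return p.v0 + (p.v - p.v0) * xn / (p.K ** p.n + xn)


def activity_placm(lactose: float, params: CircuitParams) -> float:
    """Lactose-activated placm activity (a.u./h)."""
    if lactose < 0:
        raise ValueError(f"lactose must be >= 0, got {lactose!r}")
    return _hill_activation(lactose, params.placm)


def activity_patp2(pH: float, params: CircuitParams) -> float:
    """patp2 activity (a.u./h): repressed by protons, so weakened by a pH drop."""
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must lie in (0, 14), got {pH!r}")
    p = params.patp2
    h = 10.0 ** (-pH)
    Kn = p.K ** p.n
    return p.v0 + (p.v - p.v0) * Kn / (Kn + h ** p.n)


def hill_repression(repressor: float, v: float, v0: float, K: float, n: float) -> float:
    """Hill repression v0 + (v - v0) K^n / (K^n + r^n); value in [v0, v]."""
    if repressor < 0:
        raise ValueError(f"repressor must be >= 0, got {repressor!r}")
    Kn = K ** n
    return v0 + (v - v0) * Kn / (Kn + repressor ** n)


def activity_pRE(cII: float, params: CircuitParams) -> float:
    """cII-activated pRE activity (a.u./h)."""
    if cII < 0:
        raise ValueError(f"cII must be >= 0, got {cII!r}")
    return _hill_activation(cII, params.pRE)


def cii_degradation_rate(cIII: float, params: CircuitParams) -> float:
    """Effective cII degradation rate (1/h); FtsH term is inhibited by cIII."""
    if cIII < 0:
        raise ValueError(f"cIII must be >= 0, got {cIII!r}")
    Km = params.K_cIII ** params.m_cIII
    return params.delta_cII + params.delta_ftsh * Km / (Km + cIII ** params.m_cIII)


def _rhs_array(x: np.ndarray, signals: SignalInput, p: CircuitParams) -> np.ndarray:
    """Derivatives on the raw state vector (order of STATE_VARS)."""
    cI, cro, cII, cIII, beta_gal, l_ldh = x
    cI, cro, cII, cIII = max(cI, 0.0), max(cro, 0.0), max(cII, 0.0), max(cIII, 0.0)
    a_atp2 = activity_patp2(signals.pH, p)
    a_lacm = activity_placm(signals.lactose, p)
    a_pre = activity_pRE(cII, p)
    a_pr = hill_repression(cI, p.pR.v, p.pR.v0, p.pR.K, p.pR.n)
    a_prm = hill_repression(cro, p.pRM.v, p.pRM.v0, p.pRM.K, p.pRM.n)
    return np.array([
        a_atp2 - p.delta_cI * cI,
        a_lacm + a_pre - p.delta_cro * cro,
        a_lacm + a_pre - cii_degradation_rate(cIII, p) * cII,
        a_pr - p.delta_cIII * cIII,
        a_prm - p.delta_gal * beta_gal,
        a_pr - p.delta_ldh * l_ldh,
    ])


def circuit_rhs(state: RegulatorState, signals: SignalInput, params: CircuitParams) -> RegulatorState:
    """Time derivative of the regulator state under fixed signals."""
    x = state.as_array()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite regulator state")
    dx = _rhs_array(x, signals, params)
    # derivatives may be negative; bypass the non-negativity check
    out = RegulatorState.__new__(RegulatorState)
    for k, v in zip(STATE_VARS, dx):
        object.__setattr__(out, k, float(v))
    return out


def simulate_circuit(initial, signal_fn, params: CircuitParams, t_grid,
                     rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the circuit ODEs under a time-varying signal.

    Parameters
    ----------
    initial : RegulatorState
    signal_fn : callable t -> SignalInput
    t_grid : strictly increasing array of output times (h)

    Returns
    -------
    pandas.DataFrame in tidy form (time_h, variable, value).
    """
    import pandas as pd

    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    def f(t, x):
        return _rhs_array(x, signal_fn(t), params)

    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), initial.as_array(),
                    method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"circuit integration failed: {sol.message}")
    y = sol.y
    if np.any(y < -1e-12):
        raise RuntimeError("integration produced negative concentrations beyond tolerance")
    y = np.clip(y, 0.0, None)
    rows = []
    for i, var in enumerate(STATE_VARS):
        rows.append(pd.DataFrame({"time_h": t_grid, "variable": var, "value": y[i]}))
    return pd.concat(rows, ignore_index=True)


def _jacobian(x: np.ndarray, signals: SignalInput, params: CircuitParams,
              rel_step: float = 1e-6) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (_rhs_array(xp, signals, params) - _rhs_array(xm, signals, params)) / (xp[j] - xm[j])
    return J


def find_stable_states(signals: SignalInput, params: CircuitParams,
                       n_starts: int = 20, seed: int = 0,
                       tol: float = 1e-9, dedup_tol: float = 1e-6) -> list[RegulatorState]:
    """Locate stable fixed points by seeded multi-start root finding.

    Initial guesses are drawn log-uniformly over [1e-3, 1e3] a.u.; converged
    roots are kept when the residual is below `tol` and all Jacobian
    eigenvalues (central finite differences) have negative real part, then
    deduplicated at L-infinity distance `dedup_tol`.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)] + [10.0 ** rng.uniform(-3, 3, size=6) for _ in range(n_starts - 1)]

    found: list[np.ndarray] = []
    for x0 in starts:
        res = root(lambda x: _rhs_array(x, signals, params), x0, method="hybr",
                   options={"xtol": 1e-12})
        if not res.success:
            continue
        x = np.clip(res.x, 0.0, None)
        if np.max(np.abs(_rhs_array(x, signals, params))) > tol:
            continue
        eig = np.linalg.eigvals(_jacobian(x, signals, params))
        if np.max(eig.real) >= 0:
            continue
        if any(np.max(np.abs(x - y)) < dedup_tol for y in found):
            continue
        found.append(x)
    found.sort(key=lambda x: tuple(x))
    return [RegulatorState.from_array(x) for x in found]
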