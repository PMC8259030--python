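"""Gut-lumen / culture-medium chemistry coupled to the switch circuit.

Tracks extracellular lactose, lactate and pyruvate (mM) and community
biomass (OD-equivalent units).  pH is not a state variable: it is derived
from the lactate pool through a saturating depression map and fed back to
the circuit as a signal, closing the loop

    lactose --(fermentation)--> lactate --> pH drop --> circuit switches
    to L-LDH --> lactate oxidised to pyruvate --> pH recovers.

Scenario harnesses reproduce the two experimental designs as simulations:
a 12-h in-vitro culture at three initial pH set points, and a 6-h in-vivo
mouse experiment with a lactose gavage at t=0 and four arms (untreated,
model, control, test).  Only the "test" arm carries the engineered circuit;
the "control" arm carries biomass with native β-galactosidase only, and
the model/untreated arms receive no engineered bacteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuit import (
    CircuitParams,
    RegulatorState,
    SignalInput,
    STATE_VARS,
    _rhs_array,
    find_stable_states,
)

__all__ = [
    "LumenState",
    "EnvParams",
    "Scenario",
    "ARMS",
    "LACTOSE_MW",
    "ph_from_lactate",
    "lactate_from_ph",
    "dose_to_concentration",
    "reaction_fluxes",
    "coupled_rhs",
    "run_scenario",
    "compare_arms",
    "default_env",
    "preset_scenarios",
    "PRESET_NAMES",
]

ARMS = ("test", "control", "model", "untreated")
LACTOSE_MW = 342.30  # g/mol
A_SAT = 2.0  # mM; half-saturation of acid-removal terms in lactate


@dataclass(frozen=True)
class LumenState:
    """Extracellular pools: lactose, lactate, pyruvate (mM) and biomass (OD)."""

    lactose: float
    lactate: float
    pyruvate: float = 0.0
    biomass: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lactose", "lactate", "pyruvate", "biomass"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class EnvParams:
    """Lumen chemistry parameters.

    pH is mapped from lactate as pH_ref - eta * A / (kappa + A); enzyme
    fluxes are Michaelis-Menten, scaled by biomass and (for the engineered
    enzymes) by the circuit's expression level.  ``Z_native`` is the native
    β-galactosidase baseline carried by the non-engineered arms.
    """

    pH_ref: float = 7.0      # acid-free reference pH
    eta: float = 3.0         # maximal pH depression (pH units)
    kappa: float = 20.0      # lactate giving half depression (mM)
    V_gal: float = 1.0       # hydrolysis Vmax per unit enzyme per OD (mM/h)
    K_gal: float = 5.0       # hydrolysis Km (mM lactose)
    V_ldh: float = 0.3       # lactate oxidation Vmax per unit enzyme per OD (mM/h)
    K_ldh: float = 10.0      # LDH Km (mM lactate)
    V_ferm: float = 0.2      # community fermentation Vmax per OD (mM/h)
    K_ferm: float = 20.0     # fermentation Km (mM lactose)
    y_lac: float = 4.0       # mol lactate per mol lactose fermented (homolactic)
    k_alk: float = 0.56      # base production per OD (mM lactate neutralised /h)
    k_up: float = 1.0        # pyruvate uptake rate per OD (1/h)
    mu_max: float = 0.4      # max specific growth rate (1/h)
    B_max: float = 6.0       # carrying capacity (OD)
    pH_opt: float = 7.0      # growth pH optimum
    sigma_pH: float = 2.0    # width of the Gaussian growth-pH penalty
    Z_native: float = 0.1    # native β-GAL baseline, a.u.

    def __post_init__(self) -> None:
        for name in ("eta", "kappa", "V_gal", "K_gal", "V_ldh", "K_ldh", "V_ferm",
                     "K_ferm", "k_alk", "k_up", "mu_max", "B_max", "sigma_pH",
                     "Z_native"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (1.0 <= self.y_lac <= 4.0):
            raise ValueError("y_lac must lie in [1, 4]")


def default_env(setting: str = "in_vitro") -> EnvParams:
    """Default chemistry for the two experimental settings.

    The in-vitro defaults describe an adjusted LB culture (reference pH 7,
    large buffered lactate pools, growing culture from OD ~2).  The in-vivo
    defaults describe the mouse colon lumen: reference pH 5, dense resident
    community, slow net growth, faster effective LDH turnover.
    """
    if setting == "in_vitro":
        return EnvParams()
    if setting == "in_vivo":
        return EnvParams(pH_ref=5.0, eta=1.2, kappa=30.0, V_ldh=0.7, K_ldh=10.0,
                         V_ferm=2.5, K_ferm=20.0, k_alk=2.0, mu_max=0.1,
                         B_max=12.0, pH_opt=6.0, sigma_pH=2.0)
    raise ValueError(f"unknown setting {setting!r}")


def ph_from_lactate(lactate: float, params: EnvParams) -> float:
    """pH under a lactate load: pH_ref - eta * A / (kappa + A)."""
    if lactate < 0:
        raise ValueError(f"lactate must be >= 0, got {lactate!r}")
    return params.pH_ref - params.eta * lactate / (params.kappa + lactate)


def lactate_from_ph(pH: float, params: EnvParams) -> float:
    """Invert ph_from_lactate; defined for pH in (pH_ref - eta, pH_ref]."""
    d = params.pH_ref - pH
    if d < 0 or d >= params.eta:
        raise ValueError(
            f"pH {pH!r} outside invertible range ({params.pH_ref - params.eta}, "
            f"{params.pH_ref}]")
    return params.kappa * d / (params.eta - d)


def dose_to_concentration(dose_mg: float, lumen_volume_ml: float = 0.4) -> float:
    """Map a lactose dose (mg) to an initial lumen concentration (mM)."""
    return dose_mg / LACTOSE_MW / (lumen_volume_ml * 1e-3)


def _effective_enzymes(regulators: RegulatorState, arm: str, params: EnvParams):
    if arm == "test":
        return regulators.beta_gal, regulators.l_ldh
    if arm in ("control", "model", "untreated"):
        return params.Z_native, 0.0
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def reaction_fluxes(lumen: LumenState, regulators: RegulatorState, arm: str,
                    params: EnvParams) -> dict[str, float]:
    """Lumen reaction fluxes (mM/h), all non-negative.

    hydrolysis       β-GAL lactose hydrolysis (no acid produced)
    fermentation     community fermentation of lactose to lactate
    ldh_oxidation    L-LDH lactate -> pyruvate (test arm only)
    alkalinization   basal lactate neutralisation by community metabolism
    pyruvate_uptake  pyruvate import for the TCA cycle (pure sink)
    """
    beta_gal, l_ldh = _effective_enzymes(regulators, arm, params)
    L, A, P, B = lumen.lactose, lumen.lactate, lumen.pyruvate, lumen.biomass
    return {
        "hydrolysis": params.V_gal * beta_gal * B * L / (params.K_gal + L),
        "fermentation": params.V_ferm * B * L / (params.K_ferm + L),
        "ldh_oxidation": params.V_ldh * l_ldh * B * A / (params.K_ldh + A),
        "alkalinization": params.k_alk * B,
        "pyruvate_uptake": params.k_up * P * B,
    }


def coupled_rhs(lumen: LumenState, regulators: RegulatorState, arm: str,
                env: EnvParams, circuit: CircuitParams) -> tuple[np.ndarray, np.ndarray]:
    """Joint derivative of (lumen, regulators) under the closed loop.

    Returns (d_lumen, d_regulators) as arrays ordered like
    (lactose, lactate, pyruvate, biomass) and STATE_VARS.  The lactate
    derivative is floored at zero acid: removal terms cannot drive A < 0.
    """
    x = np.array([lumen.lactose, lumen.lactate, lumen.pyruvate, lumen.biomass,
                  *regulators.as_array()])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite joint state")
    d = _coupled_rhs_array(x, arm, env, circuit)
    return d[:4], d[4:10]


def _coupled_rhs_array(x: np.ndarray, arm: str, env: EnvParams,
                       circuit: CircuitParams) -> np.ndarray:
    """RHS on the packed vector [L, A, P, B, 6 regulators, cum_hyd, cum_ferm]."""
    L, A, P, B = (max(v, 0.0) for v in x[:4])
    regs = x[4:10]
    lumen = LumenState(lactose=L, lactate=A, pyruvate=P, biomass=B)
    reg_state = RegulatorState.from_array(np.clip(regs, 0.0, None))
    fl = reaction_fluxes(lumen, reg_state, arm, env)
    pH = ph_from_lactate(A, env)
    dL = -fl["hydrolysis"] - fl["fermentation"]
    # acid removal requires encountering the acid: removal terms carry a
    # Michaelis factor in A (half-saturation A_SAT), which also floors the
    # lactate pool at zero smoothly
    sat = A / (A + A_SAT)
    dA = env.y_lac * fl["fermentation"] - (fl["ldh_oxidation"] + fl["alkalinization"]) * sat
    if A <= 0.0:
        dA = max(dA, 0.0)
    dP = fl["ldh_oxidation"] - fl["pyruvate_uptake"]
    dB = env.mu_max * math.exp(-((pH - env.pH_opt) ** 2) / (2 * env.sigma_pH ** 2)) \
        * B * (1.0 - B / env.B_max)
    dregs = _rhs_array(regs, SignalInput(lactose=L, pH=pH), circuit)
    out = np.empty(12)
    out[:4] = (dL, dA, dP, dB)
    out[4:10] = dregs
    out[10] = fl["hydrolysis"]
    out[11] = fl["fermentation"]
    return out


@dataclass(frozen=True)
class Scenario:
    """One simulated experiment arm."""

    arm: str
    setting: str                      # "in_vitro" or "in_vivo"
    initial_pH: float
    initial_lactose: float            # mM
    duration_h: float
    sampling_interval_h: float = 0.5
    bolus: tuple = ()                 # ((time_h, lactose mM added), ...)
    initial_biomass: float = 2.0
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.setting not in ("in_vitro", "in_vivo"):
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.setting == "in_vitro" and self.arm in ("model", "untreated"):
            raise ValueError("model/untreated arms are in-vivo only")
        if self.duration_h < 0:
            raise ValueError("duration must be >= 0")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.duration_h > 0:
            k = self.duration_h / self.sampling_interval_h
            if abs(k - round(k)) > 1e-9:
                raise ValueError("sampling interval must divide the duration")
        for t, amount in self.bolus:
            if not (0 <= t <= self.duration_h) or amount < 0:
                raise ValueError(f"invalid bolus ({t}, {amount})")


def _rest_state(pH: float, circuit: CircuitParams) -> RegulatorState:
    """Circuit rest state at (lactose 0, given pH); origin relaxation fallback."""
    states = find_stable_states(SignalInput(0.0, pH), circuit, n_starts=12, seed=7)
    if states:
        return states[0]
    return RegulatorState()


def run_scenario(scenario: Scenario, env: EnvParams | None = None,
                 circuit: CircuitParams | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Simulate one scenario arm; returns a tidy wide table at sampling times.

    The initial lactate pool is inverted from the scenario's initial pH.
    For the test arm, regulators start from the circuit rest state of the
    pre-exposure condition (neutral pre-culture in vitro; the colonic pH
    in vivo, since the strain colonises for a week before the bolus).
    Bolus events are applied as instantaneous lactose increments.
    """
    env = env if env is not None else default_env(scenario.setting)
    circuit = circuit if circuit is not None else CircuitParams()

    A0 = lactate_from_ph(scenario.initial_pH, env)
    pre_pH = 7.0 if scenario.setting == "in_vitro" else scenario.initial_pH
    regs0 = _rest_state(pre_pH, circuit) if scenario.arm == "test" else RegulatorState()
    x = np.array([scenario.initial_lactose, A0, 0.0, scenario.initial_biomass,
                  *regs0.as_array(), 0.0, 0.0])

    n = int(round(scenario.duration_h / scenario.sampling_interval_h)) if scenario.duration_h > 0 else 0
    t_grid = np.linspace(0.0, scenario.duration_h, n + 1)

    events = sorted([(float(t), float(a)) for t, a in scenario.bolus])
    breakpoints = sorted({0.0, scenario.duration_h, *(t for t, _ in events)})

    rows = [x.copy()]
    out_times = [0.0]
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for t_ev, amount in events:
            if abs(t_ev - t0) < 1e-12:
                x[0] += amount
                rows[-1] = x.copy() if out_times and abs(out_times[-1] - t0) < 1e-12 else rows[-1]
        seg_t = t_grid[(t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)]
        if t1 - t0 <= 1e-12:
            continue
        sol = solve_ivp(lambda t, y: _coupled_rhs_array(y, scenario.arm, env, circuit),
                        (t0, t1), x, method="LSODA",
                        t_eval=seg_t if len(seg_t) else None, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"scenario integration failed: {sol.message}")
        for i in range(len(sol.t)):
            if len(seg_t):
                rows.append(sol.y[:, i].copy())
                out_times.append(float(sol.t[i]))
        x = sol.y[:, -1].copy()
        if not len(seg_t) or abs(out_times[-1] - t1) > 1e-9:
            # ensure state is advanced to the breakpoint even if unsampled
            x = sol.y[:, -1].copy()

    arr = np.clip(np.array(rows), 0.0, None)
    df = pd.DataFrame({
        "time_h": out_times,
        "lactose_mM": arr[:, 0],
        "lactate_mM": arr[:, 1],
        "pyruvate_mM": arr[:, 2],
        "biomass": arr[:, 3],
        **{k: arr[:, 4 + i] for i, k in enumerate(STATE_VARS)},
        "cum_hydrolysis_mM": arr[:, 10],
        "cum_fermentation_mM": arr[:, 11],
    })
    df["pH"] = [ph_from_lactate(a, env) for a in df["lactate_mM"]]
    bg_eff = [
        _effective_enzymes(RegulatorState.from_array(r), scenario.arm, env)
        for r in arr[:, 4:10]
    ]
    df["beta_gal_eff"] = [b for b, _ in bg_eff]
    df["l_ldh_eff"] = [l for _, l in bg_eff]
    df["arm"] = scenario.arm
    df["scenario_id"] = scenario.scenario_id or f"{scenario.setting}_{scenario.arm}"
    return df


def compare_arms(trajectories: list[pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Summaries across arms sharing one time grid.

    Returns ``differences`` (per-time test-control and model-untreated
    deltas of pH and effective β-GAL where both arms are present) and
    ``troughs`` (per arm: time of the pH minimum and its depth below the
    initial pH).
    """
    by_arm = {}
    grid = None
    for df in trajectories:
        arm = df["arm"].iloc[0]
        t = df["time_h"].to_numpy()
        if grid is None:
            grid = t
        elif len(t) != len(grid) or np.max(np.abs(t - grid)) > 1e-9:
            raise ValueError("trajectories do not share a time grid")
        by_arm[arm] = df.reset_index(drop=True)

    diffs = pd.DataFrame({"time_h": grid})
    for a, b in (("test", "control"), ("model", "untreated")):
        if a in by_arm and b in by_arm:
            diffs[f"pH_{a}_minus_{b}"] = by_arm[a]["pH"] - by_arm[b]["pH"]
            diffs[f"beta_gal_{a}_minus_{b}"] = (
                by_arm[a]["beta_gal_eff"] - by_arm[b]["beta_gal_eff"])

    troughs = []
    for arm, df in by_arm.items():
        i = int(np.argmin(df["pH"].to_numpy()))
        troughs.append({
            "arm": arm,
            "trough_time_h": float(df["time_h"].iloc[i]),
            "trough_pH": float(df["pH"].iloc[i]),
            "trough_depth": float(df["pH"].iloc[0] - df["pH"].iloc[i]),
            "max_abs_deviation": float(np.max(np.abs(df["pH"] - df["pH"].iloc[0]))),
        })
    return {"differences": diffs, "troughs": pd.DataFrame(troughs)}


_IN_VITRO_PH = {"pH_set_I": 4.54, "pH_set_II": 5.34, "pH_set_III": 6.25}
# 1% w/v lactose in the adjusted medium
_IN_VITRO_LACTOSE = 10.0 / LACTOSE_MW * 1000.0
_IN_VIVO_DOSE_MG = 12.0

PRESET_NAMES = (*_IN_VITRO_PH, *(f"invivo_{a}" for a in ARMS))


def preset_scenarios(name: str, lumen_volume_ml: float = 0.4) -> list[Scenario]:
    """Shipped scenario presets.

    ``pH_set_I/II/III``: 12-h in-vitro cultures (test and control arms) at
    initial pH 4.54 / 5.34 / 6.25 with 1% lactose, inoculated near OD 2.
    ``invivo_{arm}``: 6-h colon simulation; the lactose gavage (12 mg per
    20 g body weight) maps to an initial concentration via the lumen volume.
    """
    if name in _IN_VITRO_PH:
        pH0 = _IN_VITRO_PH[name]
        return [
            Scenario(arm=arm, setting="in_vitro", initial_pH=pH0,
                     initial_lactose=_IN_VITRO_LACTOSE, duration_h=12.0,
                     sampling_interval_h=0.5, initial_biomass=2.0,
                     scenario_id=f"{name}_{arm}")
            for arm in ("test", "control")
        ]
    if name.startswith("invivo_"):
        arm = name.removeprefix("invivo_")
        if arm not in ARMS:
            raise ValueError(f"unknown preset {name!r}")
        lactose = 0.0 if arm == "untreated" else dose_to_concentration(
            _IN_VIVO_DOSE_MG, lumen_volume_ml)
        return [Scenario(arm=arm, setting="in_vivo", initial_pH=5.0,
                         initial_lactose=lactose, duration_h=6.0,
                         sampling_interval_h=0.25, initial_biomass=10.0,
                         scenario_id=name)]
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
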