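"""Deterministic whole-cell KV2.1 current model with functional-fraction scaling.

A Hodgkin-Huxley-type delayed-rectifier description: one activation gate x
with a Boltzmann steady state and a bell-shaped voltage-dependent time
constant, an optional inactivation gate y, and a current density

    I/C_m = f * g_max * x(t) [* y(t)] * (V - E_K)    [pA/pF]

where f is the fraction of membrane channels that actually conduct.
Because the current is strictly linear in both f and g_max, calibrating
g_max so the fully functional (f = 1) steady-state density at a reference
voltage matches a measured/published value makes every scaled prediction
(f = 0.5, 0.1, 0.01, ...) independent of the uncalibrated gating details.

E_K defaults to the Nernst potential of the whole-cell recording solutions
(5 mM K+ external, 107 mM K+ internal) at 295 K, -77.9 mV. The default
activation parameters (V_half = +9 mV, k = 9 mV) are placeholders in the
right range for KV2.1; they are not traceable to a published parameter set
and the calibration workflow deliberately does not depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "KvModelParams",
    "VoltageProtocol",
    "IVCurve",
    "simulate_step",
    "iv_curve",
    "calibrate_gmax",
    "ry785_subtract",
    "nernst_potassium",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)

#: gating placeholders are not from a published KV2.1 parameter table
UNVERIFIED_FROM_REF_MODEL = True


def nernst_potassium(k_out_mM: float = 5.0, k_in_mM: float = 107.0,
                     temperature_K: float = 295.0) -> float:
    """K+ reversal potential (mV) from the recording solutions."""
    if k_out_mM <= 0 or k_in_mM <= 0:
        raise ValueError("ion concentrations must be positive")
    return 1000.0 * GAS_CONSTANT * temperature_K / FARADAY * np.log(k_out_mM / k_in_mM)


@dataclass(frozen=True)
class KvModelParams:
    """Conductance, gating and scaling parameters of the KV2.1 model."""

    g_max: float = 100.0  # nS/pF; rescaled by calibrate_gmax
    f_functional: float = 1.0
    E_K: float = nernst_potassium()  # mV
    V_half_act: float = 9.0  # mV
    k_act: float = 9.0  # mV
    tau_act_base_ms: float = 2.0
    tau_act_amp_ms: float = 20.0
    # optional inactivation gate; disabled when tau_inact_ms is None
    V_half_inact: float | None = None
    k_inact: float | None = None
    tau_inact_ms: float | None = None
    C_m: float = 16.0  # pF, typical arterial myocyte

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if not 0.0 <= self.f_functional <= 1.0:
            raise ValueError("f_functional must be in [0, 1]")
        if self.k_act == 0:
            raise ValueError("k_act must be nonzero")
        if self.tau_act_base_ms <= 0 or self.tau_act_amp_ms < 0:
            raise ValueError("activation time constants must be positive")

    def x_inf(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(v_mV, dtype=float) - self.V_half_act) / self.k_act))

    def tau_act(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        return self.tau_act_base_ms + self.tau_act_amp_ms / np.cosh((v - self.V_half_act) / (2.0 * self.k_act))

    def y_inf(self, v_mV):
        if self.V_half_inact is None:
            return 1.0
        return 1.0 / (1.0 + np.exp((np.asarray(v_mV, dtype=float) - self.V_half_inact) / self.k_inact))

    @property
    def has_inactivation(self) -> bool:
        return self.tau_inact_ms is not None


@dataclass(frozen=True)
class VoltageProtocol:
    """Voltage-step protocol: hold, then one step per test voltage."""

    holding_mV: float = -70.0
    step_mVs: tuple = tuple(range(-70, 80, 10))
    step_ms: float = 500.0
    dt_ms: float = 0.05

    def __post_init__(self) -> None:
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.dt_ms <= 0 or self.dt_ms > self.step_ms / 100.0:
            raise ValueError("dt_ms must be positive and <= step_ms/100")


@dataclass
class IVCurve:
    """Steady-state (late) current density per step voltage."""

    voltages_mV: np.ndarray
    densities_pA_pF: np.ndarray

    def at(self, v_mV: float) -> float:
        idx = np.nonzero(np.isclose(self.voltages_mV, v_mV))[0]
        if idx.size == 0:
            raise KeyError(f"voltage {v_mV} mV not in protocol")
        return float(self.densities_pA_pF[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"V_mV": self.voltages_mV, "I_pA_per_pF": self.densities_pA_pF})


def _check_dt(params: KvModelParams, protocol: VoltageProtocol) -> None:
    taus = [float(np.min(params.tau_act(np.array(protocol.step_mVs, dtype=float))))]
    if params.has_inactivation:
        taus.append(float(params.tau_inact_ms))
    tau_min = min(taus)
    if protocol.dt_ms > tau_min / 10.0:
        raise ValueError(
            f"dt_ms={protocol.dt_ms} too coarse for tau_min={tau_min:.3g} ms "
            f"(need dt <= tau_min/10)"
        )


def simulate_step(params: KvModelParams, protocol: VoltageProtocol) -> pd.DataFrame:
    """Integrate the gate ODEs over each voltage step; RK4, fixed step.

    The gate starts from its steady state at the holding potential. Returns
    a tidy DataFrame (time_ms, V_mV, I_pA_per_pF) with one block per step
    voltage.
    """
    _check_dt(params, protocol)
    dt = protocol.dt_ms
    n = int(round(protocol.step_ms / dt))
    t = np.arange(n + 1) * dt
    frames = []
    x0 = float(params.x_inf(protocol.holding_mV))
    y0 = float(params.y_inf(protocol.holding_mV)) if params.has_inactivation else 1.0
    for v in protocol.step_mVs:
        xinf = float(params.x_inf(v))
        taux = float(params.tau_act(v))
        # dx/dt = (xinf - x)/taux is linear; RK4 on it is effectively exact
        # at dt << tau but we keep the generic integrator for the contract
        x = np.empty(n + 1)
        x[0] = x0
        def fx(xv):
            return (xinf - xv) / taux
        for i in range(n):
            k1 = fx(x[i])
            k2 = fx(x[i] + 0.5 * dt * k1)
            k3 = fx(x[i] + 0.5 * dt * k2)
            k4 = fx(x[i] + dt * k3)
            x[i + 1] = x[i] + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        gate = x
        if params.has_inactivation:
            yinf = float(params.y_inf(v))
            tauy = float(params.tau_inact_ms)
            y = yinf + (y0 - yinf) * np.exp(-t / tauy)
            gate = x * y
        current = params.f_functional * params.g_max * gate * (v - params.E_K)
        frames.append(pd.DataFrame({"time_ms": t, "V_mV": float(v), "I_pA_per_pF": current}))
    return pd.concat(frames, ignore_index=True)


def iv_curve(params: KvModelParams, protocol: VoltageProtocol,
             late_fraction: float = 0.1) -> IVCurve:
    """Late-current density per step voltage (mean over the final 10% of the step)."""
    traces = simulate_step(params, protocol)
    volts = np.array(protocol.step_mVs, dtype=float)
    densities = np.empty(volts.size)
    t_cut = protocol.step_ms * (1.0 - late_fraction)
    for i, v in enumerate(volts):
        block = traces[np.isclose(traces["V_mV"], v)]
        late = block[block["time_ms"] >= t_cut]
        densities[i] = float(late["I_pA_per_pF"].mean())
    return IVCurve(voltages_mV=volts, densities_pA_pF=densities)


def calibrate_gmax(
    params: KvModelParams,
    target_density: float,
    at_voltage: float,
    protocol: VoltageProtocol,
) -> KvModelParams:
    """Rescale g_max so the f=1 late density at ``at_voltage`` hits the target.

    The current is exactly linear in g_max, so the calibration is a
    closed-form rescale; the returned params reproduce the target within
    floating-point precision.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    ref = replace(params, f_functional=1.0)
    base = iv_curve(ref, protocol).at(at_voltage)
    if base == 0.0:
        raise ValueError(
            f"zero open probability (or V = E_K) at {at_voltage} mV; cannot calibrate"
        )
    return replace(params, g_max=params.g_max * target_density / base)


def ry785_subtract(total_trace: pd.DataFrame, blocked_trace: pd.DataFrame) -> pd.DataFrame:
    """Pointwise difference isolating the KV2-blocker-sensitive current.

    Both traces must share the time base (and voltage labels if present);
    negative excursions are preserved.
    """
    t_tot = np.asarray(total_trace["time_ms"], dtype=float)
    t_blk = np.asarray(blocked_trace["time_ms"], dtype=float)
    if t_tot.shape != t_blk.shape or not np.allclose(t_tot, t_blk):
        raise ValueError("time bases of total and blocked traces do not match")
    out = total_trace.copy()
    out["I_pA_per_pF"] = (
        np.asarray(total_trace["I_pA_per_pF"], dtype=float)
        - np.asarray(blocked_trace["I_pA_per_pF"], dtype=float)
    )
    return out
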