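"""Single-pole RC model of the per-electrode storage capacitor.

Each array unit is a 1 pF capacitor behind an access transistor.  While
its row/column are selected the capacitor charges through the on-path
resistance ``R_on`` toward the 5 V supply; deselected, it leaks through
``R_off``.  The transistor is abstracted as an ideal switch in series
with ``R_on`` — a deliberately minimal model, but one that reproduces
both printed operating points of the chip (80 ns -> 3 V, 20 ns -> ~1 V)
with a single time constant.

``R_on`` is not assumed: it is calibrated from the (80 ns, 3 V) point at
5 V / 1 pF, giving tau_on = 87.31 ns.  ``R_off`` sets the refresh droop;
the default 2.5e11 ohm yields 2.5% droop over the 6.326 ms full-array
refresh period, comfortably inside the 5% design bound.

Refresh pulses are modelled as charge-to-target: the controller ends the
pulse once the electrode reaches the programmed voltage (a fixed-length
5 V pulse applied to a partly charged capacitor would overshoot and
ratchet the steady state toward the supply rail instead of holding the
designated level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .addressing import ArrayGeometry, Schedule, UnitAddress

__all__ = [
    "RCParams",
    "Waveform",
    "calibrate_on_resistance",
    "charge_voltage",
    "discharge_voltage",
    "steady_state_ripple",
    "waveform",
]


@dataclass(frozen=True)
class RCParams:
    """Capacitor circuit constants (SI units).

    ``R_on`` defaults to the value calibrated from the printed
    (t_on = 80 ns, V = 3 V) operating point; pass ``R_on=None`` to
    recalibrate for non-default C / V_dd.
    """

    C: float = 1e-12
    V_dd: float = 5.0
    R_on: float | None = None
    R_off: float = 2.5e11

    def __post_init__(self) -> None:
        if self.C <= 0 or self.V_dd <= 0 or self.R_off <= 0:
            raise ValueError("RC parameters must be strictly positive")
        if self.R_on is None:
            object.__setattr__(
                self,
                "R_on",
                calibrate_on_resistance(params=replace(self, R_on=1.0)),
            )
        if self.R_on <= 0:
            raise ValueError("R_on must be strictly positive")

    @property
    def tau_on(self) -> float:
        return self.R_on * self.C

    @property
    def tau_off(self) -> float:
        return self.R_off * self.C


@dataclass(frozen=True)
class Waveform:
    """Sampled voltage trace at one electrode."""

    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and voltages must be 1-D and the same length")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("times must be monotone non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)

    def to_csv(self, path) -> None:
        from .io import write_waveform_csv

        write_waveform_csv(path, self)


def calibrate_on_resistance(
    V_target: float = 3.0,
    t_on: float = 80e-9,
    params: RCParams | None = None,
) -> float:
    """On-path resistance making a ``t_on`` pulse reach ``V_target``.

    Inverts V_dd (1 - exp(-t_on / (R_on C))) = V_target:
    R_on = t_on / (C ln(V_dd / (V_dd - V_target))).
    """
    if params is None:
        params = RCParams(R_on=1.0)  # placeholder; only C, V_dd used
    if not 0 < V_target < params.V_dd:
        raise ValueError(
            f"target {V_target} V not reachable from a {params.V_dd} V supply"
        )
    if t_on <= 0:
        raise ValueError("t_on must be positive")
    return t_on / (params.C * math.log(params.V_dd / (params.V_dd - V_target)))


def charge_voltage(t_on, params: RCParams | None = None, V0: float = 0.0):
    """Capacitor voltage after charging for ``t_on`` seconds from ``V0``.

    Accepts scalars or arrays; monotone increasing in ``t_on`` and
    bounded by the supply.
    """
    params = params or RCParams()
    t = np.asarray(t_on, dtype=float)
    if np.any(t < 0):
        raise ValueError("charge time must be non-negative")
    v = params.V_dd - (params.V_dd - V0) * np.exp(-t / params.tau_on)
    return float(v) if np.isscalar(t_on) else v


def discharge_voltage(V0, t_off, params: RCParams | None = None):
    """Voltage after leaking for ``t_off`` seconds from ``V0`` through R_off."""
    params = params or RCParams()
    t = np.asarray(t_off, dtype=float)
    if np.any(t < 0):
        raise ValueError("discharge time must be non-negative")
    v = V0 * np.exp(-t / params.tau_off)
    return float(v) if np.isscalar(t_off) else v


def steady_state_ripple(
    t_on: float = 80e-9,
    t_cycle: float = 6.326e-3,
    params: RCParams | None = None,
) -> tuple[float, float, float]:
    """Periodic steady state of the refresh cycle: (V_max, V_min, droop %).

    One cycle = a charge-to-target pulse (peak = charge_voltage(t_on))
    followed by ``t_cycle - t_on`` of leakage, so
    droop = 100 (V_max - V_min) / V_max = 100 (1 - exp(-t_off/tau_off)).
    """
    params = params or RCParams()
    if t_cycle <= t_on:
        raise ValueError("t_cycle must exceed t_on")
    v_max = charge_voltage(t_on, params)
    v_min = discharge_voltage(v_max, t_cycle - t_on, params)
    droop = 100.0 * (v_max - v_min) / v_max if v_max > 0 else 0.0
    return v_max, v_min, droop


def _charge_duration(V_start: float, V_peak: float, params: RCParams) -> float:
    """Time for the RC node to rise from V_start to V_peak (charge-to-target)."""
    if V_peak <= V_start:
        return 0.0
    return params.tau_on * math.log(
        (params.V_dd - V_start) / (params.V_dd - V_peak)
    )


def waveform(
    schedule: "Schedule",
    unit: "UnitAddress",
    params: RCParams | None = None,
    geometry: "ArrayGeometry | None" = None,
    n_cycles: int = 5,
    samples_per_phase: int = 200,
) -> Waveform:
    """Voltage trace at one electrode over ``n_cycles`` refresh passes.

    The unit charges when its instance executes (at its time offset
    within the pass) and leaks for the rest of the pass.  A unit the
    schedule never selects yields a flat zero trace.
    """
    from .addressing import ArrayGeometry, scan_time

    params = params or RCParams()
    geometry = geometry or ArrayGeometry()
    t_pass = scan_time(schedule)
    if t_pass <= 0:
        raise ValueError("schedule has zero duration")

    # locate the instance charging this unit and its start time in the pass
    t_start = None
    t_on = None
    elapsed = 0.0
    for inst in schedule.instances:
        if unit in inst.units(geometry):
            t_start = elapsed
            t_on = inst.t_charge_ns * 1e-9
            break
        elapsed += inst.t_charge_ns * 1e-9

    if t_start is None:
        t = np.linspace(0.0, n_cycles * t_pass, 2 * samples_per_phase)
        return Waveform(times=t, voltages=np.zeros_like(t))

    v_peak = charge_voltage(t_on, params)
    times: list[np.ndarray] = []
    volts: list[np.ndarray] = []
    v = 0.0
    for cycle in range(n_cycles):
        base = cycle * t_pass
        # leakage from pass start until this unit's slot
        if t_start > 0:
            t = np.linspace(0.0, t_start, samples_per_phase, endpoint=False)
            times.append(base + t)
            volts.append(discharge_voltage(v, t, params))
            v = discharge_voltage(v, t_start, params)
        # charge-to-target ramp (ends early once the peak is reached)
        t_ramp = min(t_on, _charge_duration(v, v_peak, params))
        t = np.linspace(0.0, t_on, samples_per_phase, endpoint=False)
        ramp = charge_voltage(np.minimum(t, t_ramp), params, V0=v)
        times.append(base + t_start + t)
        volts.append(ramp)
        v = charge_voltage(t_ramp, params, V0=v)
        # leakage for the remainder of the pass
        t_rest = t_pass - t_start - t_on
        if t_rest > 0:
            t = np.linspace(0.0, t_rest, samples_per_phase, endpoint=False)
            times.append(base + t_start + t_on + t)
            volts.append(discharge_voltage(v, t, params))
            v = discharge_voltage(v, t_rest, params)
    return Waveform(times=np.concatenate(times), voltages=np.concatenate(volts))
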