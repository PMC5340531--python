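"""Ideal voltage-clamp simulation of channel currents.

Gates are advanced by exponential-Euler updates at fixed ``dt``::

    x <- x_inf + (x - x_inf) * exp(-dt / tau)

with ``(x_inf, tau)`` evaluated at the clamped voltage (and, for
calcium-gated channels, a fixed calcium concentration per trace).  This
update is exact for piecewise-constant voltage, so hold segments are
advanced in closed form; ramp and action-potential waveforms are scanned
sample by sample with rates taken at each interval's midpoint voltage.  Gates start at steady state for the holding
potential (the first waveform sample), which removes onset transients.

The recorded quantity is the channel's own current density
``I = gbar * prod x_i^p_i * (V - E_rev)`` in mA/cm^2 (no leak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import ChannelModel, GateSpec, KCA_CALCIUM_LEVELS, gate_steady_state
from .protocols import PROTOCOL_NAMES, VoltageProtocol, Waveform, build_all_protocols

__all__ = ["CurrentTraceSet", "run_clamp", "run_all_protocols", "traces_to_frame", "traces_from_frame"]


@dataclass(frozen=True)
class CurrentTraceSet:
    """Current responses of one channel to one protocol.

    ``traces`` has shape ``(n_traces, n_samples)``; for calcium-gated
    channels the trace index runs over calcium level (outermost, descending
    concentration) then voltage step (ascending).
    """

    channel_id: str
    protocol_name: str
    dt: float
    traces: np.ndarray
    step_voltages: tuple[float, ...]
    ca_levels: tuple[float, ...] | None
    analysis_window: tuple[float, float]

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]


def _gate_trajectory_holds(
    gate: GateSpec, waveform: Waveform, dt: float, ca: float | None
) -> np.ndarray:
    """Closed-form exponential-Euler trajectory for an all-hold waveform."""
    n_total = round(waveform.duration / dt)
    x = np.empty(n_total + 1)
    prev: float | None = None
    i0 = 0
    inf = tau = 0.0
    for seg in waveform.segments:
        n_seg = round(seg.duration / dt)
        inf, tau = gate_steady_state(gate, seg.v_start, ca=ca)
        if prev is None:  # init at steady state of the holding potential
            prev = inf
            x[0] = prev
            start = 1
        else:
            start = i0
        if n_seg > 0 and start < i0 + n_seg:
            idx = np.arange(start, i0 + n_seg)
            x[idx] = inf + (prev - inf) * np.exp(-(idx - (start - 1)) * dt / tau)
            prev = x[i0 + n_seg - 1]
        i0 += n_seg
    # final sample: one more update within the last segment
    x[n_total] = inf + (prev - inf) * np.exp(-dt / tau)
    return x


def _gate_trajectory_scan(
    gate: GateSpec, v: np.ndarray, dt: float, ca: float | None
) -> np.ndarray:
    """Per-sample exponential-Euler scan for an arbitrary voltage trace.

    Rates are evaluated at the midpoint voltage of each update interval,
    which keeps the update exact for constant stretches and second-order
    accurate on ramps.
    """
    v_mid = v.copy()
    v_mid[1:] = 0.5 * (v[:-1] + v[1:])
    inf, tau = gate_steady_state(gate, v_mid, ca=ca)
    inf = np.broadcast_to(inf, v.shape)
    tau = np.broadcast_to(tau, v.shape)
    a = np.exp(-dt / tau)
    b = inf * (1.0 - a)
    x = np.empty_like(v)
    x[0] = inf[0]
    a_l, b_l = a.tolist(), b.tolist()
    cur = float(inf[0])
    out = x.tolist()
    for i in range(1, len(out)):
        cur = a_l[i] * cur + b_l[i]
        out[i] = cur
    return np.asarray(out)


def _open_fraction(channel: ChannelModel, waveform: Waveform, dt: float, ca: float | None) -> np.ndarray:
    all_holds = waveform.samples is None and all(s.kind == "hold" for s in waveform.segments)
    v = None if all_holds else waveform.sample(dt)
    open_frac: np.ndarray | None = None
    for gate in channel.gates:
        gate_ca = ca if gate.ca_dependent else None
        if all_holds:
            x = _gate_trajectory_holds(gate, waveform, dt, gate_ca)
        else:
            x = _gate_trajectory_scan(gate, v, dt, gate_ca)
        if np.any(~np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite gate state for channel {channel.id!r}, gate {gate.name!r}"
            )
        contrib = x if gate.exponent == 1 else x**gate.exponent
        open_frac = contrib if open_frac is None else open_frac * contrib
    return open_frac


def run_clamp(
    channel: ChannelModel,
    protocol: VoltageProtocol,
    ca_levels: tuple[float, ...] | None = None,
) -> CurrentTraceSet:
    """Simulate one channel under one protocol and record current traces.

    ``ca_levels`` must be supplied (or defaulted) exactly for KCa channels;
    the default is the seven standard concentrations ``10**-x`` mM,
    x = 2.0 .. 5.0.
    """
    if channel.ion_class == "KCa":
        if ca_levels is None:
            ca_levels = KCA_CALCIUM_LEVELS
    elif ca_levels is not None:
        raise ValueError("ca_levels may only be supplied for KCa channels")

    erev = channel.erev
    dt = protocol.dt
    levels = ca_levels if ca_levels is not None else (None,)
    rows = []
    for ca in levels:
        for waveform in protocol.waveforms:
            open_frac = _open_fraction(channel, waveform, dt, ca)
            v = waveform.sample(dt)
            # gbar applied last so rescaling the conductance rescales every
            # sample exactly
            rows.append(channel.gbar * (open_frac * (v - erev)))
    traces = np.asarray(rows)
    if not np.all(np.isfinite(traces)):
        raise FloatingPointError(f"non-finite current for channel {channel.id!r}")
    return CurrentTraceSet(
        channel_id=channel.id,
        protocol_name=protocol.name,
        dt=dt,
        traces=traces,
        step_voltages=protocol.step_voltages,
        ca_levels=ca_levels,
        analysis_window=protocol.analysis_window,
    )


def run_all_protocols(
    channel: ChannelModel,
    protocols: dict[str, VoltageProtocol] | None = None,
) -> dict[str, CurrentTraceSet]:
    """All five protocol responses for a channel's ion class."""
    if protocols is None:
        protocols = build_all_protocols(channel.ion_class)
    return {name: run_clamp(channel, protocols[name]) for name in PROTOCOL_NAMES}


def traces_to_frame(traces: CurrentTraceSet) -> pd.DataFrame:
    """Tidy long-form view (protocol, step, ca_level, t_ms, current)."""
    n_traces, n_samples = traces.traces.shape
    t = np.arange(n_samples) * traces.dt
    levels = traces.ca_levels if traces.ca_levels is not None else (np.nan,)
    n_steps = n_traces // len(levels)
    frames = []
    for i in range(n_traces):
        ca = levels[i // n_steps]
        step = i % n_steps
        frames.append(
            pd.DataFrame(
                {
                    "protocol": traces.protocol_name,
                    "step": step,
                    "ca_level": ca,
                    "t_ms": t,
                    "current": traces.traces[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(
    frame: pd.DataFrame,
    channel_id: str,
    protocol: VoltageProtocol,
) -> CurrentTraceSet:
    """Rebuild a trace set from the tidy CSV schema (e.g. external recordings).

    The frame must carry columns ``protocol, step, ca_level, t_ms, current``
    on the protocol's time grid.
    """
    required = {"protocol", "step", "ca_level", "t_ms", "current"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    sub = frame[frame["protocol"] == protocol.name]
    if sub.empty:
        raise ValueError(f"no rows for protocol {protocol.name!r}")
    has_ca = sub["ca_level"].notna().any()
    rows = []
    ca_levels = []
    if has_ca:
        for ca in sorted(sub["ca_level"].unique(), reverse=True):
            ca_levels.append(ca)
            block = sub[sub["ca_level"] == ca]
            for step in sorted(block["step"].unique()):
                rows.append(block[block["step"] == step].sort_values("t_ms")["current"].to_numpy())
    else:
        for step in sorted(sub["step"].unique()):
            rows.append(sub[sub["step"] == step].sort_values("t_ms")["current"].to_numpy())
    traces = np.asarray(rows)
    expected = round(protocol.duration / protocol.dt) + 1
    if traces.shape[1] != expected:
        raise ValueError(
            f"trace length {traces.shape[1]} does not match protocol grid ({expected} samples)"
        )
    return CurrentTraceSet(
        channel_id=channel_id,
        protocol_name=protocol.name,
        dt=protocol.dt,
        traces=traces,
        step_voltages=protocol.step_voltages,
        ca_levels=tuple(ca_levels) if has_ca else None,
        analysis_window=protocol.analysis_window,
    )
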