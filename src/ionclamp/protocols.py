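"""Voltage-clamp protocol construction.

Five protocol families probe a channel's gating repertoire:

- ``activation``: a single graded voltage step from rest, capturing
  activation kinetics;
- ``inactivation``: a long graded prepulse followed by a fixed test step,
  capturing inactivation accumulated during the prepulse;
- ``deactivation``: a fixed high step followed by graded tail steps,
  capturing closing (tail-current) kinetics;
- ``ramp``: four up/down linear voltage ramp pairs at different slopes;
- ``action_potential``: a somatic spike-train waveform.

Protocol parameters differ per ion class (holding levels, step ranges,
durations and analysis windows); they are loaded from the versioned table
``data/protocols.yaml``.  Segments are left-closed/right-open: the sample
at a segment boundary belongs to the new segment.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .channels import ION_CLASSES

__all__ = [
    "PROTOCOL_NAMES",
    "Segment",
    "Waveform",
    "VoltageProtocol",
    "APWaveform",
    "protocol_table",
    "build_protocol",
    "build_all_protocols",
    "sample_waveform",
    "synthesize_ap_waveform",
]

PROTOCOL_NAMES = ("activation", "inactivation", "deactivation", "ramp", "action_potential")


@dataclass(frozen=True)
class Segment:
    """A piecewise waveform element: a hold or a linear ramp."""

    kind: str  # "hold" | "ramp"
    duration: float  # ms
    v_start: float  # mV
    v_end: float  # mV (== v_start for holds)

    @staticmethod
    def hold(v: float, duration: float) -> "Segment":
        return Segment("hold", duration, v, v)

    @staticmethod
    def ramp(v_start: float, v_end: float, duration: float) -> "Segment":
        return Segment("ramp", duration, v_start, v_end)


@dataclass(frozen=True)
class Waveform:
    """One clamped-voltage time course, as segments or explicit samples."""

    segments: tuple[Segment, ...] = ()
    samples: np.ndarray | None = None  # used for arbitrary waveforms (AP)
    duration: float = 0.0  # ms

    def sample(self, dt: float) -> np.ndarray:
        """Voltage at times ``0, dt, ..., duration`` (length round(T/dt)+1)."""
        if self.samples is not None:
            return np.asarray(self.samples, dtype=float)
        n_total = round(self.duration / dt)
        v = np.empty(n_total + 1)
        i0 = 0
        for seg in self.segments:
            n_seg = round(seg.duration / dt)
            if seg.kind == "hold":
                v[i0 : i0 + n_seg] = seg.v_start
            else:
                frac = np.arange(n_seg) / n_seg
                v[i0 : i0 + n_seg] = seg.v_start + frac * (seg.v_end - seg.v_start)
            i0 += n_seg
        # final sample: end value of the last segment
        v[n_total] = self.segments[-1].v_end
        return v


@dataclass(frozen=True)
class APWaveform:
    """A spiking voltage waveform sampled at resolution ``dt``."""

    samples: np.ndarray
    dt: float
    duration: float  # ms


@dataclass(frozen=True)
class VoltageProtocol:
    ion_class: str
    name: str
    waveforms: tuple[Waveform, ...]
    dt: float
    analysis_window: tuple[float, float]  # (TA, TB) ms
    step_voltages: tuple[float, ...] = ()

    @property
    def duration(self) -> float:
        return self.waveforms[0].duration

    @property
    def n_steps(self) -> int:
        return len(self.waveforms)


@functools.cache
def protocol_table() -> dict:
    """The versioned protocol parameter table bundled with the package."""
    text = resources.files("ionclamp.data").joinpath("protocols.yaml").read_text()
    return yaml.safe_load(text)


def _step_range(v_lo: float, v_hi: float, dv: float) -> tuple[float, ...]:
    n = round((v_hi - v_lo) / dv) + 1
    return tuple(v_lo + i * dv for i in range(n))


def synthesize_ap_waveform(
    duration: float = 1800.0,
    spike_rate: float = 10.0,
    seed: int = 0,
    dt: float = 0.05,
) -> APWaveform:
    """Synthetic regular-spiking somatic voltage waveform.

    A deterministic stand-in for an experimentally recorded spike train:
    resting potential -65 mV, stereotyped spikes (0.4 ms depolarization to
    +30 mV, 1.2 ms repolarization to a -72 mV afterhyperpolarization,
    exponential recovery with a 15 ms time constant) at regular intervals
    set by ``spike_rate`` with small seeded timing jitter.  ``spike_rate``
    of 0 yields a constant baseline.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = round(duration / dt) + 1
    t = np.arange(n) * dt
    v = np.full(n, -65.0)
    if spike_rate > 0:
        interval = 1000.0 / spike_rate
        base_times = np.arange(interval / 2.0, duration, interval)
        jitter = rng.uniform(-2.0, 2.0, size=base_times.size)
        spike_times = np.clip(base_times + jitter, 0.0, duration - 2.0)
        rise, fall, tau_ahp = 0.4, 1.2, 15.0
        peak, ahp = 30.0, -72.0
        for t0 in spike_times:
            rel = t - t0
            m_rise = (rel >= 0) & (rel < rise)
            m_fall = (rel >= rise) & (rel < rise + fall)
            m_ahp = rel >= rise + fall
            v[m_rise] = -65.0 + (peak + 65.0) * rel[m_rise] / rise
            v[m_fall] = peak + (ahp - peak) * (rel[m_fall] - rise) / fall
            v[m_ahp] = np.minimum(
                v[m_ahp], -65.0 + (ahp + 65.0) * np.exp(-(rel[m_ahp] - rise - fall) / tau_ahp)
            )
    return APWaveform(samples=v, dt=dt, duration=duration)


def build_protocol(
    ion_class: str,
    name: str,
    ap_waveform: APWaveform | None = None,
) -> VoltageProtocol:
    """Construct the clamp protocol for one (ion class, protocol) pair.

    ``ap_waveform`` overrides the bundled synthetic spike train for the
    action-potential protocol (e.g. a user-supplied somatic recording).
    """
    table = protocol_table()
    if ion_class not in ION_CLASSES or name not in PROTOCOL_NAMES:
        raise KeyError(f"unknown protocol ({ion_class!r}, {name!r})")
    row = table["protocols"][name][ion_class]
    dt = float(table["dt"])
    window = (float(row["TA"]), float(row["TB"]))

    if name == "action_potential":
        wf = ap_waveform or synthesize_ap_waveform(duration=float(row["T1"]), dt=dt)
        if abs(wf.duration - float(row["T1"])) > 1e-9:
            raise ValueError(
                f"AP waveform duration {wf.duration} ms does not match table ({row['T1']} ms)"
            )
        waveform = Waveform(samples=wf.samples, duration=wf.duration)
        return VoltageProtocol(ion_class, name, (waveform,), dt, window)

    if name == "ramp":
        v0, v1 = float(row["V0"]), float(row["V1"])
        durations = [float(x) for x in row["T"]]
        segs = [Segment.hold(v0, durations[0])]
        lo, hi = v0, v1
        for d in durations[1:]:
            segs.append(Segment.ramp(lo, hi, d))
            lo, hi = hi, lo
        waveform = Waveform(segments=tuple(segs), duration=sum(durations))
        return VoltageProtocol(ion_class, name, (waveform,), dt, window)

    v0 = float(row["V0"])
    dv = float(row["dV"])
    t = [float(row[f"T{i}"]) for i in (1, 2, 3) + (() if name == "activation" else (4,))]
    if name == "activation":
        steps = _step_range(float(row["V1"]), float(row["V2"]), dv)
        waveforms = tuple(
            Waveform(
                segments=(Segment.hold(v0, t[0]), Segment.hold(vs, t[1]), Segment.hold(v0, t[2])),
                duration=sum(t),
            )
            for vs in steps
        )
    elif name == "inactivation":
        steps = _step_range(float(row["V1"]), float(row["V2"]), dv)
        v3 = float(row["V3"])
        waveforms = tuple(
            Waveform(
                segments=(
                    Segment.hold(v0, t[0]),
                    Segment.hold(vs, t[1]),
                    Segment.hold(v3, t[2]),
                    Segment.hold(v0, t[3]),
                ),
                duration=sum(t),
            )
            for vs in steps
        )
    else:  # deactivation
        steps = _step_range(float(row["V2"]), float(row["V3"]), dv)
        v1 = float(row["V1"])
        waveforms = tuple(
            Waveform(
                segments=(
                    Segment.hold(v0, t[0]),
                    Segment.hold(v1, t[1]),
                    Segment.hold(vs, t[2]),
                    Segment.hold(v0, t[3]),
                ),
                duration=sum(t),
            )
            for vs in steps
        )
    return VoltageProtocol(ion_class, name, waveforms, dt, window, steps)


def build_all_protocols(
    ion_class: str, ap_waveform: APWaveform | None = None
) -> dict[str, VoltageProtocol]:
    """All five protocols for one ion class, keyed by protocol name."""
    return {name: build_protocol(ion_class, name, ap_waveform) for name in PROTOCOL_NAMES}


def sample_waveform(protocol: VoltageProtocol, step_index: int) -> np.ndarray:
    """Voltage samples of one graded step (length ``round(T/dt) + 1``)."""
    if not 0 <= step_index < len(protocol.waveforms):
        raise IndexError(f"step index {step_index} out of range")
    return protocol.waveforms[step_index].sample(protocol.dt)
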