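"""Hodgkin-Huxley-style ion-channel models.

A channel is a maximal conductance ``gbar`` times a product of gating
variables raised to integer powers, times the driving force ``V - E_rev``::

    I(t) = gbar * prod_i x_i(t)**p_i * (V(t) - E_rev)      [mA/cm^2]

Each gating variable relaxes with first-order kinetics
``dx/dt = (x_inf(V) - x) / tau(V)``.  Rates are expressed in a closed-form
family (exponential, sigmoid and linoid terms for ``alpha``/``beta``;
Boltzmann ``x_inf`` with constant or bell-shaped ``tau``), which is
sufficient for classical HH-style channel descriptions and keeps models
declarative and serializable.  Calcium-gated (KCa) activation uses a Hill
function of the intracellular calcium concentration.

Rates are taken as already valid at the simulation temperature of 37 degC
(``q10_factor`` defaults to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ION_CLASSES",
    "IonClassDefaults",
    "ION_CLASS_DEFAULTS",
    "GateSpec",
    "ChannelModel",
    "nernst_potential",
    "gate_steady_state",
    "rate_value",
    "validate_gate",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

ION_CLASSES = ("Kv", "Nav", "Cav", "KCa", "Ih")

#: voltage range (mV) on which gate invariants must hold
GATE_VALIDATION_RANGE = (-150.0, 70.0)

#: half-width (mV) around a linoid singularity inside which the analytic
#: limit A*k is used instead of the raw expression
LINOID_EPS = 1e-6


def nernst_potential(z: int, conc_in: float, conc_out: float, temperature: float = 37.0) -> float:
    """Nernst reversal potential in mV.

    Parameters
    ----------
    z : int
        Ion valence (nonzero).
    conc_in, conc_out : float
        Intra-/extracellular concentrations in mM (positive).
    temperature : float
        Temperature in degrees Celsius.
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("ion valence must be nonzero")
    t_kelvin = temperature + 273.15
    volts = GAS_CONSTANT * t_kelvin / (z * FARADAY) * math.log(conc_out / conc_in)
    return volts * 1e3


@dataclass(frozen=True)
class IonClassDefaults:
    """Per-ion-class simulation parameters (reversal potential, concentrations)."""

    erev: float  # mV
    conc_in: float | None  # mM
    conc_out: float | None  # mM
    valence: int | None
    temperature: float = 37.0  # degC
    dt: float = 0.05  # ms
    ca_levels: tuple[float, ...] = ()  # mM, KCa only


#: intracellular calcium levels (mM) for KCa simulations: 10**-x,
#: x in {2.0, 2.5, ..., 5.0}, in descending concentration order
KCA_CALCIUM_LEVELS = tuple(10.0 ** -x for x in (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0))

ION_CLASS_DEFAULTS: dict[str, IonClassDefaults] = {
    "Kv": IonClassDefaults(erev=-86.7, conc_in=85.0, conc_out=3.3152396, valence=1),
    "Nav": IonClassDefaults(erev=50.0, conc_in=21.0, conc_out=136.3753955, valence=1),
    "Cav": IonClassDefaults(erev=135.0, conc_in=8.1929e-5, conc_out=2.0, valence=2),
    "KCa": IonClassDefaults(
        erev=-86.7, conc_in=85.0, conc_out=3.3152396, valence=1, ca_levels=KCA_CALCIUM_LEVELS
    ),
    "Ih": IonClassDefaults(erev=-45.0, conc_in=None, conc_out=None, valence=None),
}


# ---------------------------------------------------------------------------
# rate-function family
# ---------------------------------------------------------------------------

def rate_value(term: dict[str, Any], v: np.ndarray | float) -> np.ndarray | float:
    """Evaluate one closed-form rate term at membrane voltage ``v`` (mV).

    Supported forms (parameters ``A`` 1/ms, ``Vh`` mV, ``k`` mV):

    - ``constant``:   A
    - ``exp``:        A * exp((V - Vh) / k)
    - ``sigmoid``:    A / (1 + exp((V - Vh) / k))
    - ``linoid``:     A * (V - Vh) / (exp((V - Vh) / k) - 1), with the
      removable singularity at V = Vh evaluated by its limit A*k.
    """
    form = term["form"]
    v = np.asarray(v, dtype=float)
    if form == "constant":
        return np.broadcast_to(np.asarray(term["A"], dtype=float), v.shape).copy() if v.ndim else float(term["A"])
    A = float(term["A"])
    vh = float(term["Vh"])
    k = float(term["k"])
    x = (v - vh) / k
    if form == "exp":
        out = A * np.exp(x)
    elif form == "sigmoid":
        out = A / (1.0 + np.exp(x))
    elif form == "linoid":
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            raw = A * (v - vh) / np.expm1(x)
        out = np.where(np.abs(v - vh) < LINOID_EPS, A * k, raw)
    else:
        raise ValueError(f"unknown rate form {form!r}")
    return float(out) if out.ndim == 0 else out


def _bell_tau(params: dict[str, Any], v: np.ndarray | float) -> np.ndarray | float:
    """Bell-shaped time constant: base + amp / (exp((V-Vh)/k1) + exp(-(V-Vh)/k2))."""
    v = np.asarray(v, dtype=float)
    base = float(params.get("base", 0.0))
    amp = float(params["amp"])
    vh = float(params["Vh"])
    k1 = float(params["k1"])
    k2 = float(params["k2"])
    out = base + amp / (np.exp((v - vh) / k1) + np.exp(-(v - vh) / k2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GateSpec:
    """One gating variable ``x`` entering the open fraction as ``x**exponent``.

    ``rate_form`` selects between an ``alpha_beta`` parameterization
    (``rate_params = {"alpha": term, "beta": term}``) and an ``inf_tau``
    parameterization (``rate_params = {"inf": {...}, "tau": {...}}``).
    ``inf`` is a Boltzmann ``1/(1 + exp(-(V - Vh)/k))`` (``k < 0`` gives an
    inactivation gate), or, for calcium-dependent gates, a Hill function
    ``ca**h / (ca**h + Kd**h)``.  ``tau`` is ``constant`` or ``bell``.
    """

    name: str
    exponent: int
    rate_form: str  # "alpha_beta" | "inf_tau"
    rate_params: dict[str, Any] = field(default_factory=dict)
    ca_dependent: bool = False
    q10_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent < 1 or int(self.exponent) != self.exponent:
            raise ValueError("gate exponent must be a positive integer")
        if self.rate_form not in ("alpha_beta", "inf_tau"):
            raise ValueError(f"unknown rate_form {self.rate_form!r}")
        if self.q10_factor <= 0:
            raise ValueError("q10_factor must be positive")


def gate_steady_state(
    gate: GateSpec, v: np.ndarray | float, ca: float | None = None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Steady state ``x_inf`` and time constant ``tau`` (ms) at voltage ``v``.

    ``ca`` (mM) must be supplied exactly when ``gate.ca_dependent`` is set.
    For ``alpha_beta`` gates the standard conversion ``x_inf = a/(a+b)``,
    ``tau = 1/(a+b)`` applies; the ``q10_factor`` scales both rates, i.e.
    divides ``tau`` and leaves ``x_inf`` untouched.
    """
    if gate.ca_dependent and ca is None:
        raise ValueError(f"gate {gate.name!r} is calcium-dependent; ca must be supplied")
    if not gate.ca_dependent and ca is not None:
        raise ValueError(f"gate {gate.name!r} is not calcium-dependent; ca must be omitted")

    if gate.rate_form == "alpha_beta":
        a = rate_value(gate.rate_params["alpha"], v)
        b = rate_value(gate.rate_params["beta"], v)
        total = a + b
        inf = a / total
        tau = 1.0 / total
    else:
        inf_p = gate.rate_params["inf"]
        if gate.ca_dependent:
            kd = float(inf_p["Kd"])
            h = float(inf_p.get("hill", 1.0))
            frac = ca**h / (ca**h + kd**h)
            inf = np.broadcast_to(frac, np.shape(v)).copy() if np.ndim(v) else frac
        else:
            vh = float(inf_p["Vh"])
            k = float(inf_p["k"])
            varr = np.asarray(v, dtype=float)
            inf = 1.0 / (1.0 + np.exp(-(varr - vh) / k))
            inf = float(inf) if inf.ndim == 0 else inf
        tau_p = gate.rate_params["tau"]
        if tau_p["form"] == "constant":
            tau = np.full(np.shape(v), float(tau_p["value"])) if np.ndim(v) else float(tau_p["value"])
        elif tau_p["form"] == "bell":
            tau = _bell_tau(tau_p, v)
        else:
            raise ValueError(f"unknown tau form {tau_p['form']!r}")
    if gate.q10_factor != 1.0:
        tau = tau / gate.q10_factor
    return inf, tau


def validate_gate(gate: GateSpec, ca: float | None = None, n_points: int = 256) -> None:
    """Check gate invariants on the validation voltage range.

    Raises ``ValueError`` if ``x_inf`` leaves [0, 1] or ``tau`` is not
    strictly positive anywhere on [-150, 70] mV.
    """
    v = np.linspace(*GATE_VALIDATION_RANGE, n_points)
    ca_arg = ca if gate.ca_dependent else None
    if gate.ca_dependent and ca_arg is None:
        ca_arg = KCA_CALCIUM_LEVELS[0]
    inf, tau = gate_steady_state(gate, v, ca=ca_arg)
    inf = np.broadcast_to(inf, v.shape)
    tau = np.broadcast_to(tau, v.shape)
    if not np.all(np.isfinite(inf)) or not np.all(np.isfinite(tau)):
        raise ValueError(f"gate {gate.name!r}: non-finite inf/tau on validation range")
    if np.any(inf < -1e-12) or np.any(inf > 1 + 1e-12):
        raise ValueError(f"gate {gate.name!r}: x_inf leaves [0, 1]")
    if np.any(tau <= 0):
        raise ValueError(f"gate {gate.name!r}: tau not strictly positive")


@dataclass(frozen=True)
class ChannelModel:
    """A voltage- (and optionally calcium-) gated channel model.

    ``erev_spec`` is either ``{"erev": mV}`` (fixed reversal potential) or
    ``{"valence": z, "conc_in": mM, "conc_out": mM}`` for Nernst
    computation at the simulation temperature.  ``inward`` records the sign
    convention of the dominant physiological current; it does not enter the
    current equation, whose sign follows the driving force.
    """

    id: str
    ion_class: str
    gates: tuple[GateSpec, ...]
    erev_spec: dict[str, float] = field(default_factory=dict)
    gbar: float = 1.0  # S/cm^2
    inward: bool = False
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.ion_class not in ION_CLASSES:
            raise ValueError(f"unknown ion class {self.ion_class!r}")
        if self.gbar <= 0:
            raise ValueError("gbar must be positive")
        object.__setattr__(self, "gates", tuple(self.gates))
        n_ca = sum(g.ca_dependent for g in self.gates)
        if self.ion_class == "KCa" and n_ca < 1:
            raise ValueError("KCa models need at least one calcium-dependent gate")
        if self.ion_class != "KCa" and n_ca > 0:
            raise ValueError(f"{self.ion_class} models must not have calcium-dependent gates")

    @property
    def erev(self) -> float:
        """Reversal potential (mV), fixed or via the Nernst equation."""
        if "erev" in self.erev_spec:
            return float(self.erev_spec["erev"])
        defaults = ION_CLASS_DEFAULTS[self.ion_class]
        return nernst_potential(
            int(self.erev_spec["valence"]),
            float(self.erev_spec["conc_in"]),
            float(self.erev_spec["conc_out"]),
            defaults.temperature,
        )

    def validate(self) -> None:
        for gate in self.gates:
            validate_gate(gate)

    def with_gbar(self, gbar: float) -> "ChannelModel":
        return replace(self, gbar=gbar)

    def with_id(self, new_id: str) -> "ChannelModel":
        return replace(self, id=new_id)


def default_erev_spec(ion_class: str) -> dict[str, float]:
    """Nernst-based reversal spec from the per-class defaults (fixed for Ih)."""
    d = ION_CLASS_DEFAULTS[ion_class]
    if d.conc_in is None:
        return {"erev": d.erev}
    return {"valence": d.valence, "conc_in": d.conc_in, "conc_out": d.conc_out}
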