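"""Template channel library.

A small set of classical HH-style channel models spanning the five ion
classes (Kv, Nav, Cav, KCa, Ih).  Kinetic parameters are representative
textbook values for each phenotype, expressed in the closed-form rate
family of :mod:`ionclamp.channels`; they are meant as structured, documented
starting points for ensemble generation, not as fits to any one published
model.

Subtype labels follow common electrophysiology usage: ``HH`` (squid-axon
delayed rectifier), ``A-type`` (transient inactivating K), ``dr`` (sustained
delayed rectifier), ``m-type`` (slow muscarinic-modulated K), ``D-type``
(fast-activating slowly-inactivating K), ``Nav`` (m3h sodium), ``T-type``
(low-threshold calcium), ``SK`` (calcium-activated K), ``HCN``
(hyperpolarization-activated cation).
"""

from __future__ import annotations

from .channels import ChannelModel, GateSpec, default_erev_spec

__all__ = ["template_library", "get_template"]


def _ab(form: str, A: float, Vh: float = 0.0, k: float = 1.0) -> dict:
    if form == "constant":
        return {"form": form, "A": A}
    return {"form": form, "A": A, "Vh": Vh, "k": k}


def _boltzmann_gate(
    name: str,
    exponent: int,
    vh: float,
    k: float,
    tau: dict,
) -> GateSpec:
    return GateSpec(
        name=name,
        exponent=exponent,
        rate_form="inf_tau",
        rate_params={"inf": {"Vh": vh, "k": k}, "tau": tau},
    )


def _bell(amp: float, vh: float, k1: float, k2: float, base: float) -> dict:
    return {"form": "bell", "amp": amp, "Vh": vh, "k1": k1, "k2": k2, "base": base}


def template_library() -> list[ChannelModel]:
    """Return the documented template channels (at least one per ion class)."""
    lib: list[ChannelModel] = []

    # -- Kv: squid-axon delayed rectifier, n^4 with classic alpha/beta rates
    n_gate = GateSpec(
        name="n",
        exponent=4,
        rate_form="alpha_beta",
        rate_params={
            "alpha": _ab("linoid", -0.01, -55.0, -10.0),
            "beta": _ab("exp", 0.125, -65.0, -80.0),
        },
    )
    lib.append(
        ChannelModel(
            id="kv_hh", ion_class="Kv", gates=(n_gate,),
            erev_spec=default_erev_spec("Kv"), subtype="HH",
        )
    )

    # -- Kv: A-type, fast transient (activation m^3 plus inactivation h)
    lib.append(
        ChannelModel(
            id="kv_a",
            ion_class="Kv",
            gates=(
                _boltzmann_gate("m", 3, -30.0, 12.0, _bell(2.0, -40.0, 20.0, 20.0, 0.4)),
                _boltzmann_gate("h", 1, -70.0, -6.0, _bell(40.0, -70.0, 15.0, 15.0, 5.0)),
            ),
            erev_spec=default_erev_spec("Kv"),
            subtype="A-type",
        )
    )

    # -- Kv: sustained delayed rectifier (no inactivation)
    lib.append(
        ChannelModel(
            id="kv_dr",
            ion_class="Kv",
            gates=(_boltzmann_gate("n", 2, -15.0, 10.0, _bell(20.0, -30.0, 20.0, 20.0, 1.0)),),
            erev_spec=default_erev_spec("Kv"),
            subtype="dr",
        )
    )

    # -- Kv: m-type, slow non-inactivating muscarinic K current
    lib.append(
        ChannelModel(
            id="kv_m",
            ion_class="Kv",
            gates=(_boltzmann_gate("m", 1, -35.0, 10.0, _bell(150.0, -35.0, 15.0, 15.0, 20.0)),),
            erev_spec=default_erev_spec("Kv"),
            subtype="m-type",
        )
    )

    # -- Kv: D-type, fast-activating but slowly inactivating
    lib.append(
        ChannelModel(
            id="kv_d",
            ion_class="Kv",
            gates=(
                _boltzmann_gate("m", 1, -50.0, 20.0, _bell(4.0, -50.0, 25.0, 25.0, 1.0)),
                GateSpec(
                    name="h",
                    exponent=1,
                    rate_form="inf_tau",
                    rate_params={
                        "inf": {"Vh": -70.0, "k": -6.0},
                        "tau": {"form": "constant", "value": 500.0},
                    },
                ),
            ),
            erev_spec=default_erev_spec("Kv"),
            subtype="D-type",
        )
    )

    # -- Nav: classic m^3 h sodium channel
    m_gate = GateSpec(
        name="m",
        exponent=3,
        rate_form="alpha_beta",
        rate_params={
            "alpha": _ab("linoid", -0.1, -40.0, -10.0),
            "beta": _ab("exp", 4.0, -65.0, -18.0),
        },
    )
    h_gate = GateSpec(
        name="h",
        exponent=1,
        rate_form="alpha_beta",
        rate_params={
            "alpha": _ab("exp", 0.07, -65.0, -20.0),
            "beta": _ab("sigmoid", 1.0, -35.0, -10.0),
        },
    )
    lib.append(
        ChannelModel(
            id="nav_hh", ion_class="Nav", gates=(m_gate, h_gate),
            erev_spec=default_erev_spec("Nav"), inward=True, subtype="Nav",
        )
    )

    # -- Cav: low-threshold transient (T-type) calcium channel, m^2 h
    lib.append(
        ChannelModel(
            id="cav_t",
            ion_class="Cav",
            gates=(
                _boltzmann_gate("m", 2, -57.0, 6.2, _bell(10.0, -57.0, 16.0, 16.0, 0.6)),
                _boltzmann_gate("h", 1, -81.0, -4.0, _bell(200.0, -81.0, 15.0, 15.0, 15.0)),
            ),
            erev_spec=default_erev_spec("Cav"),
            inward=True,
            subtype="T-type",
        )
    )

    # -- KCa: small-conductance calcium-activated K (SK-like), Hill activation
    lib.append(
        ChannelModel(
            id="kca_sk",
            ion_class="KCa",
            gates=(
                GateSpec(
                    name="z",
                    exponent=1,
                    rate_form="inf_tau",
                    rate_params={
                        "inf": {"Kd": 3e-4, "hill": 4.0},  # mM
                        "tau": {"form": "constant", "value": 20.0},
                    },
                    ca_dependent=True,
                ),
            ),
            erev_spec=default_erev_spec("KCa"),
            subtype="SK",
        )
    )

    # -- Ih: hyperpolarization-activated cation current (HCN-like)
    lib.append(
        ChannelModel(
            id="ih_hcn",
            ion_class="Ih",
            gates=(_boltzmann_gate("q", 1, -75.0, -5.5, _bell(1000.0, -75.0, 15.0, 15.0, 30.0)),),
            erev_spec=default_erev_spec("Ih"),
            inward=True,
            subtype="HCN",
        )
    )

    for model in lib:
        model.validate()
    return lib


def get_template(template_id: str) -> ChannelModel:
    """Look up a template by id."""
    for model in template_library():
        if model.id == template_id:
            return model
    raise KeyError(f"no template named {template_id!r}")
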