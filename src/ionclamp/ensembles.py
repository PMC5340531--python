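"""Synthetic channel ensembles with known ground truth.

Real channel-model corpora contain many variants of a few kinetic
phenotypes, differing by small shifts in half-activation voltages and
rescaled rates (refits to different preparations and temperatures).  The
generator emulates this: each ensemble member is a template with jittered
rate parameters — half-voltages shifted additively (scale
``jitter_fraction * 20 mV``), rates, slopes and time constants rescaled
log-normally (sigma ``jitter_fraction``) — so every member stays within
its template's phenotype while the ensemble has realistic within-group
spread.  The source template of each member is the ground-truth label for
cluster-recovery checks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelModel, GateSpec, validate_gate

__all__ = ["EnsembleSpec", "generate_ensemble", "jitter_channel"]

#: additive half-voltage jitter scale, mV per unit jitter_fraction
VOLTAGE_JITTER_SCALE = 20.0

#: bounded retries when a jittered gate violates its invariants
MAX_RETRIES = 20


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic ensemble of one ion class."""

    templates: tuple[ChannelModel, ...]
    n_per_template: int = 10
    jitter_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_template < 1:
            raise ValueError("n_per_template must be at least 1")
        if self.jitter_fraction < 0:
            raise ValueError("jitter_fraction must be nonnegative")
        classes = {t.ion_class for t in self.templates}
        if len(classes) > 1:
            raise ValueError(f"templates span multiple ion classes: {sorted(classes)}")


_VOLTAGE_KEYS = {"Vh"}
_MULTIPLICATIVE_KEYS = {"A", "k", "k1", "k2", "amp", "base", "value", "Kd", "hill"}


def _jitter_params(params: dict, jitter: float, rng: np.random.Generator) -> dict:
    out = {}
    for key, val in params.items():
        if isinstance(val, dict):
            out[key] = _jitter_params(val, jitter, rng)
        elif key in _VOLTAGE_KEYS:
            out[key] = float(val) + rng.normal(0.0, jitter * VOLTAGE_JITTER_SCALE)
        elif key in _MULTIPLICATIVE_KEYS and isinstance(val, (int, float)):
            out[key] = float(val) * float(np.exp(rng.normal(0.0, jitter)))
        else:
            out[key] = copy.deepcopy(val)
    return out


def jitter_channel(
    template: ChannelModel,
    jitter_fraction: float,
    rng: np.random.Generator,
    new_id: str,
) -> ChannelModel:
    """One perturbed copy of a template, revalidated with bounded retries."""
    for _ in range(MAX_RETRIES):
        gates = []
        ok = True
        for gate in template.gates:
            cand = GateSpec(
                name=gate.name,
                exponent=gate.exponent,
                rate_form=gate.rate_form,
                rate_params=_jitter_params(gate.rate_params, jitter_fraction, rng),
                ca_dependent=gate.ca_dependent,
                q10_factor=gate.q10_factor,
            )
            try:
                validate_gate(cand)
            except ValueError:
                ok = False
                break
            gates.append(cand)
        if ok:
            return replace(template, id=new_id, gates=tuple(gates))
    raise RuntimeError(
        f"could not generate a valid jittered copy of template {template.id!r} "
        f"after {MAX_RETRIES} attempts"
    )


def generate_ensemble(spec: EnsembleSpec) -> tuple[list[ChannelModel], dict[str, str]]:
    """Generate the ensemble; returns (members, ground-truth template per id)."""
    rng = np.random.default_rng(spec.seed)
    members: list[ChannelModel] = []
    truth: dict[str, str] = {}
    for template in spec.templates:
        for i in range(spec.n_per_template):
            new_id = f"{template.id}__v{i:03d}"
            member = jitter_channel(template, spec.jitter_fraction, rng, new_id)
            members.append(member)
            truth[new_id] = template.id
    return members, truth
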