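"""Reading and writing channel definitions and tabular results.

Channel definition files are YAML documents (one channel per document,
multi-document streams allowed) with a versioned schema mirroring
:class:`~ionclamp.channels.ChannelModel`::

    schema_version: 1
    id: kv_hh
    ion_class: Kv
    gbar: 1.0
    inward: false
    subtype: HH
    erev_spec: {valence: 1, conc_in: 85.0, conc_out: 3.3152396}
    gates:
      - name: n
        exponent: 4
        rate_form: alpha_beta
        ca_dependent: false
        q10_factor: 1.0
        rate_params: {alpha: {...}, beta: {...}}

Round-tripping a channel through ``write_channels``/``read_channels`` is
lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .channels import ChannelModel, GateSpec

__all__ = ["channel_to_dict", "channel_from_dict", "read_channels", "write_channels"]

SCHEMA_VERSION = 1


def channel_to_dict(channel: ChannelModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "id": channel.id,
        "ion_class": channel.ion_class,
        "gbar": channel.gbar,
        "inward": channel.inward,
        "subtype": channel.subtype,
        "erev_spec": dict(channel.erev_spec),
        "gates": [
            {
                "name": g.name,
                "exponent": g.exponent,
                "rate_form": g.rate_form,
                "ca_dependent": g.ca_dependent,
                "q10_factor": g.q10_factor,
                "rate_params": g.rate_params,
            }
            for g in channel.gates
        ],
    }


def channel_from_dict(doc: dict) -> ChannelModel:
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported channel schema version {version}")
    gates = tuple(
        GateSpec(
            name=g["name"],
            exponent=int(g["exponent"]),
            rate_form=g["rate_form"],
            rate_params=g["rate_params"],
            ca_dependent=bool(g.get("ca_dependent", False)),
            q10_factor=float(g.get("q10_factor", 1.0)),
        )
        for g in doc["gates"]
    )
    return ChannelModel(
        id=doc["id"],
        ion_class=doc["ion_class"],
        gates=gates,
        erev_spec=doc.get("erev_spec", {}),
        gbar=float(doc.get("gbar", 1.0)),
        inward=bool(doc.get("inward", False)),
        subtype=doc.get("subtype", ""),
    )


def write_channels(channels: list[ChannelModel], path: str | Path) -> None:
    docs = [channel_to_dict(c) for c in channels]
    with open(path, "w") as fh:
        yaml.safe_dump_all(docs, fh, sort_keys=False)


def read_channels(path: str | Path) -> list[ChannelModel]:
    with open(path) as fh:
        return [channel_from_dict(doc) for doc in yaml.safe_load_all(fh) if doc]


def write_ground_truth(truth: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"channel_id": list(truth), "template_id": list(truth.values())}
    ).to_csv(path, index=False)


def scores_to_frame(ids: list[str], scores) -> pd.DataFrame:
    import numpy as np

    scores = np.asarray(scores)
    cols = {f"dim_{i + 1}": scores[:, i] for i in range(scores.shape[1])}
    return pd.DataFrame({"channel_id": ids, **cols})
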