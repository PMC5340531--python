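import numpy as np
import pytest

import ionclamp as ic

KV_TEMPLATE_IDS = ("kv_hh", "kv_a", "kv_dr", "kv_m", "kv_d")


@pytest.fixture(scope="session")
def kv_protocols():
    return ic.build_all_protocols("Kv")


@pytest.fixture(scope="session")
def recovery_ensemble(kv_protocols):
    """Five Kv templates x 10 jittered members (1% jitter, fixed seed),
    simulated, preprocessed and scored — the shared synthetic corpus."""
    templates = tuple(ic.get_template(t) for t in KV_TEMPLATE_IDS)
    spec = ic.EnsembleSpec(templates=templates, n_per_template=10,
                           jitter_fraction=0.01, seed=42)
    members, truth = ic.generate_ensemble(spec)
    features = {
        m.id: ic.preprocess_all(ic.run_all_protocols(m, kv_protocols), kv_protocols)
        for m in members
    }
    space = ic.fit_score_space(features)
    return {
        "members": members,
        "truth": truth,
        "features": features,
        "space": space,
    }
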