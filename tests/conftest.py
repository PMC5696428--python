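import numpy as np
import pytest

import flightfit as ff


@pytest.fixture(scope="session")
def scale_matched_dists():
    """One distribution per family, location-matched at 1 h (grid defaults)."""
    out = {}
    for fam in ff.FAMILIES:
        fixed = {"q": 1.6} if fam == "qexponential" else (
            {"shape": 0.7} if fam == "gamma" else {}
        )
        params, matched = ff.solve_params_for_scale(fam, 1.0, fixed=fixed)
        out[fam] = ff.make_distribution(fam, params)
    return out


@pytest.fixture(scope="session")
def gamma_record_10s():
    """A 3,000-flight gamma record observed at 10 s (shared across tests)."""
    params, _ = ff.solve_params_for_scale("gamma", 1.0, fixed={"shape": 0.7})
    dist = ff.make_distribution("gamma", params)
    flights = ff.sample_flights(dist, 3000, seed=42)
    return dist, ff.emulate_record(flights, ff.SCHEME_10S, seed=43)
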