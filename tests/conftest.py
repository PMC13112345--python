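import numpy as np
import pandas as pd
import pytest

import titramem as tm


@pytest.fixture
def asp_model():
    return tm.asp_like()


@pytest.fixture
def his_model():
    return tm.his_like()


@pytest.fixture
def flat_acid():
    return tm.flat_model(residue_class="acid", pKa_w=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def conditional_records(
    model,
    ph_values,
    n_per=2000,
    n_replicates=3,
    z_lo_A=-13.0,
    z_hi_A=23.0,
    seed=7,
    equilibrated=True,
):
    """Synthetic record table drawn from the model's exact protonation
    conditional at uniformly distributed positions: the oracle input for
    the profiling pipeline."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for pH in ph_values:
            z = rng.uniform(z_lo_A / 10.0, z_hi_A / 10.0, size=n_per)
            p_dep = model.analytic_deprot_fraction(z, pH)
            dep = rng.random(n_per) < p_dep
            rows.append(
                pd.DataFrame(
                    {
                        "time": np.arange(n_per, dtype=float),
                        "replica_id": f"rep{rep}-pH{pH:g}",
                        "replicate_index": rep,
                        "pH": float(pH),
                        "window_id": "",
                        "z_nm": z,
                        "state": np.where(dep, tm.DEPROTONATED, tm.PROTONATED),
                        "bias_kJmol": 0.0,
                        "equilibration_flag": False if equilibrated else True,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
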