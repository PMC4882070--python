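import numpy as np
import pandas as pd
import pytest

from famlipid.config import PanelSpec, SimulationConfig
from famlipid.pedigree import validate_pedigree
from famlipid.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_population=1500,
        n_families=6,
        seed=7,
        panel=PanelSpec(n_ldl=20, n_tg=20, n_omim=8),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def trio_pedigree():
    """Two parents and two full siblings."""
    return validate_pedigree(
        pd.DataFrame(
            {
                "family_id": ["A"] * 4,
                "individual_id": ["dad", "mom", "kid1", "kid2"],
                "father_id": [None, None, "dad", "dad"],
                "mother_id": [None, None, "mom", "mom"],
                "sex": ["M", "F", "M", "F"],
                "proband": [False, False, True, False],
            }
        )
    )


def sib_pedigree(n_families: int, n_kids: int, rng) -> pd.DataFrame:
    """Nuclear families: two founder parents, n_kids full siblings."""
    rows = []
    for f in range(n_families):
        fid = f"F{f}"
        rows.append((fid, f"{fid}_p1", None, None, "M", False))
        rows.append((fid, f"{fid}_p2", None, None, "F", False))
        for k in range(n_kids):
            rows.append(
                (
                    fid,
                    f"{fid}_c{k}",
                    f"{fid}_p1",
                    f"{fid}_p2",
                    "M" if rng.random() < 0.5 else "F",
                    False,
                )
            )
    return validate_pedigree(
        pd.DataFrame(
            rows,
            columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "proband"],
        )
    )
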