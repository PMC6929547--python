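import csv
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psewave import load_scales
from psewave.sequences import AMINO_ACIDS

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scales():
    return load_scales()


@pytest.fixture(scope="session")
def scale_dict():
    """Residue -> (h1, h2, h3), recomputed spreadsheet-style from the packaged
    raw CSV with the csv module (independent of psewave.scales)."""
    with resources.as_file(
        resources.files("psewave.data").joinpath("property_scales.csv")
    ) as p, open(p) as fh:
        rows = list(csv.DictReader(fh))
    cols = {}
    for name in ("hydrophobicity", "hydrophilicity", "side_chain_mass"):
        raw = {r["residue"]: float(r[name]) for r in rows}
        mean = sum(raw.values()) / 20.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in raw.values()) / 20.0)
        cols[name] = {aa: (raw[aa] - mean) / sd for aa in raw}
    return {
        aa: (cols["hydrophobicity"][aa], cols["hydrophilicity"][aa],
             cols["side_chain_mass"][aa])
        for aa in AMINO_ACIDS
    }


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
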