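import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyte.core import DonorMeta, FractionCountMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# A 6-gene, 2-male/2-female toy matrix exercising the interesting cases:
# a flat gene, a strong male-polysome effect gene, an infinite-TR donor,
# an all-zero (undefined) donor, a high-CV gene, and a bulk filler gene.
# Counts are small integers so every downstream quantity is hand-computable
# with exact rational arithmetic (see oracle_toy.py).
TOY_GENES = ["g1", "g2", "g3", "g4", "g5", "g6"]
TOY_DONORS = [
    DonorMeta("M1", "male"),
    DonorMeta("M2", "male"),
    DonorMeta("F1", "female"),
    DonorMeta("F2", "female"),
]
# counts[gene][donor] = (free, monosome, early, late)
TOY_COUNTS = {
    "g1": {"M1": (10, 10, 10, 10), "M2": (10, 10, 10, 10), "F1": (10, 10, 10, 10), "F2": (10, 10, 10, 10)},
    "g2": {"M1": (5, 5, 40, 50), "M2": (6, 4, 42, 48), "F1": (40, 40, 10, 10), "F2": (38, 42, 11, 9)},
    "g3": {"M1": (10, 10, 10, 10), "M2": (0, 0, 30, 30), "F1": (10, 10, 10, 10), "F2": (10, 10, 10, 10)},
    "g4": {"M1": (20, 10, 10, 10), "M2": (18, 12, 10, 10), "F1": (20, 10, 10, 10), "F2": (0, 0, 0, 0)},
    "g5": {"M1": (40, 40, 5, 5), "M2": (5, 5, 40, 40), "F1": (20, 20, 20, 20), "F2": (25, 25, 15, 15)},
    "g6": {"M1": (100, 100, 100, 100), "M2": (100, 100, 100, 100), "F1": (100, 100, 100, 100), "F2": (100, 100, 100, 100)},
}


def build_toy_matrix() -> FractionCountMatrix:
    counts = np.array(
        [[TOY_COUNTS[g][d.donor_id] for d in TOY_DONORS] for g in TOY_GENES],
        dtype=np.int64,
    )
    return FractionCountMatrix(genes=list(TOY_GENES), donors=list(TOY_DONORS), counts=counts)


@pytest.fixture
def toy_matrix() -> FractionCountMatrix:
    return build_toy_matrix()
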