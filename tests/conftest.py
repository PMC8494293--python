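import numpy as np
import pytest

from parbclamp import RateSet

MIN_PER_S = 1.0 / 60.0


@pytest.fixture
def discussion_rates() -> RateSet:
    """The headline parameterization: hydrolysis ~1/min, parS-catalyzed
    closure ~1/s, slow spontaneous transitions off DNA."""
    return RateSet(
        k_oc=0.001,
        k_co=0.001,
        k_oc_dna=1.0,
        k_co_dna=0.0,
        k_h=MIN_PER_S,
        kd_open=1.0,
    )


@pytest.fixture
def generic_rates() -> RateSet:
    """A moderate, non-degenerate rate set for dynamic solvers."""
    return RateSet(
        k_oc=0.2,
        k_co=0.1,
        k_oc_dna=1.0,
        k_co_dna=0.05,
        k_h=0.3,
        kd_open=1.0,
        k_on=5.0,
    )


def weighted_std(centers: np.ndarray, weights: np.ndarray) -> float:
    mu = np.average(centers, weights=weights)
    return float(np.sqrt(np.average((centers - mu) ** 2, weights=weights)))
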