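import itertools

import pytest
from hypothesis import HealthCheck, settings

from ecoconverge import build_matrix
from ecoconverge.cp_scoring import HarmonizedScore

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ALL_SCORES = (-2, -1, 0, 1, 2)


def make_score(source, site, habitat, direction, score):
    return HarmonizedScore(
        source=source, site=site, habitat=habitat, direction=direction,
        score=score, n=10 if source == "NS" else 100,
        raw_median=float(score) if source == "CP" else None,
    )


@pytest.fixture
def matrix12():
    """3 sites x 2 habitats x 2 directions, all pairings complete.

    Scores are a deterministic pattern covering the full -2..+2 range on
    both strands.
    """
    sites = ("A", "B", "C")
    habitats = ("fisheries", "mangrove")
    directions = ("past", "future")
    ns, cp = [], []
    for k, (site, habitat, direction) in enumerate(
        itertools.product(sites, habitats, directions)
    ):
        ns.append(make_score("NS", site, habitat, direction, ALL_SCORES[k % 5]))
        cp.append(make_score("CP", site, habitat, direction, ALL_SCORES[(k * 3 + 1) % 5]))
    return build_matrix(ns, cp), ns, cp
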