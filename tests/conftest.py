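import numpy as np
import pytest

from emmoa.data import StimulusSpec
from emmoa.objectives import EvaluationLedger, ObjectiveBackend
from emmoa.synthetic import SynthConfig, generate_mi_epochs, generate_ssvep_epochs


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def mi_epochs(synth_config):
    return generate_mi_epochs(synth_config, seed=0)


@pytest.fixture(scope="session")
def ssvep_bundle(synth_config):
    return generate_ssvep_epochs(synth_config, seed=1)


@pytest.fixture(scope="session")
def ssvep_epochs(ssvep_bundle):
    return ssvep_bundle[0]


@pytest.fixture(scope="session")
def stim(ssvep_bundle) -> StimulusSpec:
    return ssvep_bundle[1]


@pytest.fixture
def make_backend(mi_epochs, ssvep_epochs, stim):
    """Factory for a fresh ledger-backed objective backend."""

    def _make(budget: int = 10000) -> ObjectiveBackend:
        return ObjectiveBackend(mi_epochs, ssvep_epochs, stim,
                                EvaluationLedger(budget=budget))

    return _make


def brute_force_non_dominated(points) -> list[int]:
    """Independent O(n^2) pairwise-dominance oracle (maximization)."""
    pts = [tuple(p) for p in points]
    keep = []
    for i, a in enumerate(pts):
        dominated = False
        for j, b in enumerate(pts):
            if j == i:
                continue
            if all(bv >= av for av, bv in zip(a, b)) and any(
                    bv > av for av, bv in zip(a, b)):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep
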