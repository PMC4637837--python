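import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from supramol.assembly import build_all_models
from supramol.elements import build_element_dataset
from supramol.fixtures import FixtureSpec, make_chain, make_toy_complex
from supramol.network import cluster_subnetworks
from supramol.sequences import InteractionRecord, ProteinEntry


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def helix30():
    return make_chain("PHEL", "ADKLVEQRITNGFYSMWHCPADKLVEQRIT", "helix")


@pytest.fixture(scope="session")
def star_bundle():
    """Clash-free 4-subunit star with ground truth."""
    return make_toy_complex(FixtureSpec(seed=101, n_proteins=4, topology="star"))


@pytest.fixture(scope="session")
def star_pipeline(star_bundle):
    """Elements, sub-network and assembled model for the star fixture."""
    b = star_bundle
    elements, tally = build_element_dataset(b.interactions, b.proteins, b.library)
    nets = cluster_subnetworks(elements)
    models = build_all_models(nets[0], elements)
    return {"bundle": b, "elements": elements, "tally": tally,
            "nets": nets, "models": models}


@pytest.fixture(scope="session")
def category_bundle():
    """Star fixture extended with interactions covering all four categories.

    Structured star edges give three complex-category pairs; an added edge
    between two structure-bearing leaves is independent; an edge to a
    sequence-only protein is one-sided; an edge between two sequence-only
    proteins is unknown.
    """
    b = make_toy_complex(FixtureSpec(seed=33, n_proteins=4, topology="star"))
    proteins = dict(b.proteins)
    rng = np.random.default_rng(77)
    from supramol.fixtures import _distinct_sequence
    from supramol.config import DEFAULT

    existing = [p.sequence for p in proteins.values()]
    for acc in ("Q901", "Q902"):
        seq = _distinct_sequence(rng, 30, existing, DEFAULT)
        proteins[acc] = ProteinEntry(acc, seq)
        existing.append(seq)
    interactions = list(b.interactions) + [
        InteractionRecord("P002", "P003", "two hybrid", "IXIND"),
        InteractionRecord("P004", "Q901", "two hybrid", "IXONE"),
        InteractionRecord("Q901", "Q902", "two hybrid", "IXUNK"),
    ]
    return {"bundle": b, "proteins": proteins, "interactions": interactions}
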