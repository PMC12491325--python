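"""Shared fixtures: toy repertoires and session-scoped simulated data."""

from __future__ import annotations

import pytest

from thymosig import simulate as sim
from thymosig.io import Clonotype, Repertoire


def make_repertoire(seqs, sample_id="toy", chain="TRB", counts=None,
                    v="TRBV9", j="TRBJ2-1"):
    counts = counts or [1] * len(seqs)
    return Repertoire(
        sample_id, chain,
        [Clonotype(s, v, j, c) for s, c in zip(seqs, counts)],
    )


@pytest.fixture
def toy_repertoire():
    return make_repertoire(["CASSF", "CASTF", "CASSY", "WYQGG"])


@pytest.fixture(scope="session")
def trb_params():
    return sim.default_params("TRB")


@pytest.fixture(scope="session")
def pre_10k(trb_params):
    """A 10,000-clonotype pre-selection repertoire (shared; do not mutate)."""
    return sim.generate_pre_selection(trb_params, 10000, seed=101, sample_id="pre10k")


@pytest.fixture(scope="session")
def pre_50k(trb_params):
    """A 50,000-clonotype pre-selection repertoire (shared; do not mutate)."""
    return sim.generate_pre_selection(trb_params, 50000, seed=202, sample_id="pre50k")
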