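"""Shared fixtures: reference guides and small planted UTRome fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from seedsafe import Guide
from seedsafe import synthgen

#: a 22-nt reference guide (the let-7 mature sequence, a convenient standard)
LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

NTS = "ACGU"


@pytest.fixture(scope="session")
def let7() -> Guide:
    return Guide("let7", LET7)


@pytest.fixture(scope="session")
def warm_thermo():
    """Compile the folding kernels once per session."""
    from seedsafe import thermo

    thermo.duplex_energy("GCGCGC", "GCGCGC")
    thermo.opening_energy("A" * 40, (10, 15), flank=10)
    return thermo


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(NTS[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def planted_fixture(let7):
    """20-gene UTRome with 5 planted 8mer sites in distinct genes."""
    utrome, _ = synthgen.generate_utrome(
        20, (300, 500), gc=0.45, cpg_depletion=0.8, rng_seed=11
    )
    genes = [f"G{i:04d}" for i in (1, 4, 7, 12, 18)]
    spec = [(g, "8mer") for g in genes]
    planted, truth = synthgen.plant_sites(utrome, let7, spec, rng_seed=11)
    return planted, truth, genes
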