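"""Shared fixtures: handcrafted lookup tables and a simulated corpus whose
bond-angle means vary sinusoidally with (φ, ψ)."""

import math

import numpy as np
import pytest
from hypothesis import settings

import cdlkit as ck
from cdlkit.cdl_library import CDLKey, CDLTable, default_svl

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def ncac_mu(phi: float, psi: float) -> float:
    """True conformation-dependent N-CA-C mean used by the simulated corpus."""
    return 111.0 + 5.0 * math.sin(math.radians(phi)) * math.cos(math.radians(psi))


NCAC_NOISE = 1.2  # degrees


@pytest.fixture(scope="session")
def svl_table() -> CDLTable:
    return ck.svl_only_table()


@pytest.fixture(scope="session")
def rung_table() -> CDLTable:
    """Table exercising every lookup fallback rung: an exact hit, a
    low-count cell that must fall through, general-class cells, and the SVL
    slice."""
    entries = {
        # rung 1: exact (IleVal, False) hit at bin (-70, -50)
        (CDLKey("IleVal", False), (-70.0, -50.0), "N-CA-C"): (110.0, 1.0, 50),
        # low-count cell at bin (-60, -50): must fall through to General
        (CDLKey("IleVal", False), (-60.0, -50.0), "N-CA-C"): (108.0, 1.0, 5),
        (CDLKey("General", False), (-60.0, -50.0), "N-CA-C"): (112.0, 1.1, 40),
        # rung 2: (General, next_is_pro=True) at bin (-70, -50)
        (CDLKey("General", True), (-70.0, -50.0), "N-CA-C"): (113.0, 0.9, 30),
    }
    return CDLTable(entries=entries, svl=default_svl(), min_count=20)


@pytest.fixture(scope="session")
def sinusoid_corpus():
    """Corpus with a known sinusoidal N-CA-C surface, ≥200 accepted
    observations per populated 10° bin over the sampled 4×4-bin region."""
    spec = ck.CorpusSpec(
        n_structures=450,
        length=12,
        phi_psi={"kind": "uniform", "phi": (-70.0, -30.0), "psi": (-50.0, -10.0)},
        mu={"N-CA-C": ncac_mu},
        noise={"N-CA-C": NCAC_NOISE},
        resolution=0.9,
        seed=1234,
    )
    return ck.simulate_corpus(spec)


@pytest.fixture(scope="session")
def sinusoid_table(sinusoid_corpus) -> CDLTable:
    structures, _ = sinusoid_corpus
    return ck.build_table(structures, ck.BuilderConfig())
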